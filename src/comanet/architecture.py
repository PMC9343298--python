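"""The fixed 3D-CNN architecture: shape arithmetic, parameter accounting, builder.

The network is a 3D AlexNet/VGG-style cascade used to discriminate
comatose patients from controls on single-index whole-brain volumes:

* Conv(32, k=3, s=1, valid) + BN + ELU, AvgPool(3, s=3)
* Conv(64) + BN + ELU, Conv(64) + BN + ELU, AvgPool(2, s=2)
* Conv(128) + BN + ELU (x3), AvgPool(2, s=2)
* Flatten
* FC(512) + BN + ELU + Dropout(0.5)
* FC(512) + BN + ELU + Dropout(0.25) (x2)
* FC(512) + BN + ELU
* FC(2) + Softmax

Valid convolutions shrink every spatial dimension by 2; pooling divides
by its stride with floor semantics.  The smallest admissible input is
62 voxels per dimension (final spatial shape (1,1,1), flatten 128).
On the common 2-mm template grid (91, 109, 91) the flatten length is
4608 and the network holds 4,432,386 parameters, 4,427,202 of them
trainable (BN running statistics are the non-trainable remainder).
"""

from __future__ import annotations

import numpy as np

from .exceptions import ShapeError
from .nn.layers import AvgPool3D, BatchNorm, Conv3D, Dense, Dropout, ELU, Flatten
from .nn.network import Sequential

KERNEL = 3
CONV_CHANNELS = (32, 64, 64, 128, 128, 128)
#: pool size (== stride) applied after the given 1-based conv block
POOL_AFTER = {1: 3, 3: 2, 6: 2}
FC_UNITS = (512, 512, 512, 512)
DROPOUT_RATES = (0.5, 0.25, 0.25, None)
N_CLASSES = 2
MIN_INPUT_DIM = 62


def layer_output_shapes(input_shape: tuple[int, int, int]):
    """Spatial shape after every conv/pool stage plus the flatten length.

    Returns ``(stages, flatten_length)`` where ``stages`` is a list of
    ``(stage_name, shape)``.  Raises :class:`ShapeError` naming the first
    stage whose output would have a non-positive dimension.
    """
    dims = tuple(int(d) for d in input_shape)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise ShapeError(f"input shape must be 3 positive integers, got {input_shape}")
    stages: list[tuple[str, tuple[int, int, int]]] = []
    for i, _channels in enumerate(CONV_CHANNELS, start=1):
        dims = tuple(d - (KERNEL - 1) for d in dims)
        if any(d < 1 for d in dims):
            raise ShapeError(f"conv{i} output shape {dims} has a non-positive dimension")
        stages.append((f"conv{i}", dims))
        if i in POOL_AFTER:
            s = POOL_AFTER[i]
            dims = tuple(d // s for d in dims)
            if any(d < 1 for d in dims):
                raise ShapeError(f"pool after conv{i} output shape {dims} "
                                 f"has a non-positive dimension")
            stages.append((f"pool{i}", dims))
    flatten = int(np.prod(dims)) * CONV_CHANNELS[-1]
    return stages, flatten


def count_parameters(input_shape: tuple[int, int, int]) -> tuple[int, int]:
    """Closed-form (total, trainable) parameter counts for a given input grid.

    Conv: C_in*27*C_out weights + C_out biases.  FC: U_in*U_out + U_out.
    Every BN contributes 4 parameters per normalized channel in total
    (scale, shift, running mean, running variance), 2 of them trainable.
    """
    _, flatten = layer_output_shapes(input_shape)
    weights = 0
    bn_channels = 0
    c_in = 1
    for c_out in CONV_CHANNELS:
        weights += c_in * KERNEL ** 3 * c_out + c_out
        bn_channels += c_out
        c_in = c_out
    u_in = flatten
    for u_out in FC_UNITS:
        weights += u_in * u_out + u_out
        bn_channels += u_out
        u_in = u_out
    weights += u_in * N_CLASSES + N_CLASSES
    trainable = weights + 2 * bn_channels
    total = weights + 4 * bn_channels
    return total, trainable


def tap_geometry() -> list[tuple[float, float]]:
    """(offset, spacing) in input voxels for each conv block's output.

    A valid convolution keeps the grid spacing and shifts cell centers by
    one spacing; pooling with size s multiplies the spacing by s and
    shifts by (s-1)/2 spacings.  Cell i of a tapped map therefore sits at
    input coordinate ``offset + spacing * i`` along every axis,
    independent of the input grid size.
    """
    geoms = []
    offset, spacing = 0.0, 1.0
    for i in range(1, len(CONV_CHANNELS) + 1):
        offset += spacing  # valid conv, kernel 3
        geoms.append((offset, spacing))
        if i in POOL_AFTER:
            s = POOL_AFTER[i]
            offset += (s - 1) / 2 * spacing
            spacing *= s
    return geoms


def build_network(input_shape: tuple[int, int, int], *, rng: np.random.Generator,
                  bn_eps: float = 1e-3, bn_momentum: float | None = None,
                  dropout_rng: np.random.Generator | None = None) -> Sequential:
    """Instantiate the cascade for a given input grid.

    He-uniform initialization for conv/FC kernels (standard for the
    ELU family), BN scale 1 / shift 0.  ``dropout_rng`` defaults to
    ``rng``.  The returned network records the indices of each conv
    block's post-BN+ELU output for activation retrieval.
    """
    _, flatten = layer_output_shapes(input_shape)  # validates the grid
    drng = dropout_rng if dropout_rng is not None else rng
    layers: list = []
    taps: list[int] = []
    c_in = 1
    for i, c_out in enumerate(CONV_CHANNELS, start=1):
        layers.append(Conv3D(c_in, c_out, KERNEL, rng=rng))
        layers.append(BatchNorm(c_out, eps=bn_eps, momentum=bn_momentum))
        layers.append(ELU(inplace=True))
        taps.append(len(layers) - 1)
        if i in POOL_AFTER:
            layers.append(AvgPool3D(POOL_AFTER[i]))
        c_in = c_out
    layers.append(Flatten())
    u_in = flatten
    for u_out, rate in zip(FC_UNITS, DROPOUT_RATES):
        layers.append(Dense(u_in, u_out, rng=rng))
        layers.append(BatchNorm(u_out, eps=bn_eps, momentum=bn_momentum))
        layers.append(ELU(inplace=True))
        if rate is not None:
            layers.append(Dropout(rate, rng=drng))
        u_in = u_out
    layers.append(Dense(u_in, N_CLASSES, rng=rng))
    net = Sequential(layers)
    net.conv_tap_indices = taps
    return net
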