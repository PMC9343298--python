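"""Convolutional-filter visualization maps.

For each correctly classified training subject: retrieve the post-BN+ELU
output of each of the six convolutional blocks, keep positive
activations only, average over that block's filters, trilinearly
interpolate to the input grid, and average the six per-block maps into
one subject map.  Class maps are the averages over correctly classified
training subjects, min-max normalized to [0, 1]; their absolute
difference is the class-difference map, thresholded at half its maximum.

A Dice coefficient against the generator's injected ROI quantifies how
well the thresholded map localizes the true effect; a relocated-ROI
permutation null calibrates it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import zoom

from .architecture import tap_geometry
from .exceptions import ValidationError
from .model import CNN3DClassifier, N_CONV_LAYERS


@dataclass
class ActivationMap:
    data: np.ndarray  # non-negative, on the input grid
    subject_id: str = ""
    source: str = ""


@dataclass
class DiffMap:
    data: np.ndarray
    threshold: float | None = None
    mask: np.ndarray | None = None


def interpolate_to_grid(field: np.ndarray, grid: tuple[int, int, int],
                        offset: float | None = None,
                        spacing: float | None = None) -> np.ndarray:
    """Trilinear interpolation of a feature map onto the input grid.

    With ``offset``/``spacing`` given, cell i is placed at its
    receptive-field center ``offset + spacing * i`` (the geometrically
    faithful mapping for a valid-convolution cascade) and positions
    outside the covered span replicate the nearest cell.  Without them,
    the map is stretched across the whole grid (plain resize).  Constant
    fields stay constant under both conventions.
    """
    if offset is None or spacing is None:
        if field.shape == tuple(grid):
            return field
        factors = [t / s for t, s in zip(grid, field.shape)]
        out = zoom(field, factors, order=1, mode="nearest", grid_mode=True)
        assert out.shape == tuple(grid)
        return out
    from scipy.ndimage import map_coordinates

    axes = [(np.arange(g) - offset) / spacing for g in grid]
    coords = np.meshgrid(*axes, indexing="ij")
    return map_coordinates(field, coords, order=1, mode="nearest").astype(field.dtype)


def positive_filter_mean(acts: np.ndarray) -> np.ndarray:
    """Rectify to positive values, then average over the filter axis."""
    return np.maximum(acts, 0.0).mean(axis=0)


def layer_activation_map(clf: CNN3DClassifier, volume: np.ndarray, layer: int,
                         subject_id: str = "") -> ActivationMap:
    """One conv block's positive, filter-averaged map on the input grid."""
    acts = clf.conv_activations(volume[None], layer=layer)[0]
    offset, spacing = tap_geometry()[layer - 1]
    data = interpolate_to_grid(positive_filter_mean(acts), clf.input_shape_,
                               offset=offset, spacing=spacing)
    return ActivationMap(data=data, subject_id=subject_id, source=f"conv{layer}")


def subject_map(clf: CNN3DClassifier, volume: np.ndarray,
                subject_id: str = "") -> ActivationMap:
    """Mean of the six per-block maps (one forward pass)."""
    acts = clf.conv_activations(volume[None])
    geoms = tap_geometry()
    maps = [interpolate_to_grid(positive_filter_mean(acts[layer][0]),
                                clf.input_shape_, *geoms[layer - 1])
            for layer in range(1, N_CONV_LAYERS + 1)]
    return ActivationMap(data=np.mean(maps, axis=0), subject_id=subject_id,
                         source="conv1-6 mean")


def subject_maps(clf: CNN3DClassifier, volumes: np.ndarray,
                 batch: int = 8) -> np.ndarray:
    """Subject maps for many volumes, batched; returns (n, *input grid)."""
    acts = clf.conv_activations(volumes, batch=batch)
    n = len(volumes)
    geoms = tap_geometry()
    out = np.zeros((n, *clf.input_shape_), dtype=np.float32)
    for layer in range(1, N_CONV_LAYERS + 1):
        offset, spacing = geoms[layer - 1]
        rect = np.maximum(acts[layer], 0.0).mean(axis=1)  # filter average
        for i in range(n):
            out[i] += interpolate_to_grid(rect[i], clf.input_shape_,
                                          offset=offset, spacing=spacing)
    out /= N_CONV_LAYERS
    return out


def _minmax01(field: np.ndarray) -> np.ndarray:
    lo, hi = float(field.min()), float(field.max())
    if hi <= lo:
        return np.zeros_like(field)
    return (field - lo) / (hi - lo)


def class_difference_map(maps: np.ndarray, labels, correct,
                         normalization: str = "joint") -> DiffMap:
    """|normalized mean map of class A - normalized mean map of class B|
    over correctly classified training subjects only.

    ``normalization``:

    * ``"joint"`` (default) — min-max to [0, 1] with the minimum and
      maximum taken over *both* class maps.  A shared scale preserves
      between-class contrasts; per-map scaling can invert them when the
      two maps have different ranges, flooding the difference map with
      background.
    * ``"per_map"`` — min-max each class map independently.
    * ``"zscore"`` — standardize each class map independently.
    """
    labels = np.asarray(labels)
    correct = np.asarray(correct, dtype=bool)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError("exactly two classes required")
    class_maps = []
    for cls in classes:
        sel = (labels == cls) & correct
        if not sel.any():
            raise ValidationError(f"no correctly classified training subject in "
                                  f"class {cls!r}")
        class_maps.append(maps[sel].mean(axis=0))
    if normalization == "joint":
        lo = min(float(m.min()) for m in class_maps)
        hi = max(float(m.max()) for m in class_maps)
        span = (hi - lo) if hi > lo else 1.0
        class_maps = [(m - lo) / span for m in class_maps]
    elif normalization == "per_map":
        class_maps = [_minmax01(m) for m in class_maps]
    elif normalization == "zscore":
        class_maps = [(m - m.mean()) / (m.std() if m.std() > 0 else 1.0)
                      for m in class_maps]
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    return DiffMap(data=np.abs(class_maps[0] - class_maps[1]))


def threshold_map(diff: DiffMap) -> DiffMap:
    """Half-max threshold: voxels below max/2 are zeroed; the mask records
    which voxels survive."""
    peak = float(diff.data.max())
    if peak <= 0:
        raise ValidationError("cannot threshold an all-zero map")
    threshold = peak / 2.0
    mask = diff.data >= threshold
    data = np.where(mask, diff.data, 0.0)
    return DiffMap(data=data, threshold=threshold, mask=mask)


def localization_score(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); 0 if either is empty while
    the other is not, 1 if both are empty."""
    if mask_a.shape != mask_b.shape:
        raise ValidationError(f"grid mismatch {mask_a.shape} vs {mask_b.shape}")
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def relocated_roi_null(diff_mask: np.ndarray, semiaxes, brain_mask: np.ndarray,
                       n_permutations: int = 200, seed: int = 0) -> np.ndarray:
    """Null Dice distribution with the ROI relocated uniformly at random
    (center drawn from brain-mask voxels whose ellipsoid fits inside)."""
    from .synthetic import _ellipsoid

    rng = np.random.default_rng(seed)
    grid = diff_mask.shape
    centers = np.argwhere(brain_mask)
    fits = np.all((centers - np.asarray(semiaxes) >= 0)
                  & (centers + np.asarray(semiaxes) < np.asarray(grid)), axis=1)
    centers = centers[fits]
    if len(centers) == 0:
        raise ValidationError("no admissible relocation centers inside the mask")
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        c = centers[rng.integers(len(centers))]
        out[i] = localization_score(diff_mask, _ellipsoid(grid, c, semiaxes))
    return out


def fold_difference_maps(clf: CNN3DClassifier, x_train_norm: np.ndarray,
                         y_train, normalization: str = "joint") -> DiffMap:
    """Class-difference map for one trained fold: subject maps of the
    correctly classified training subjects, class-averaged and differenced."""
    pred = clf.predict(x_train_norm)
    correct = pred == np.asarray(y_train)
    maps = subject_maps(clf, x_train_norm)
    return class_difference_map(maps, y_train, correct, normalization=normalization)


def save_montage(diff: DiffMap, path: str | Path, title: str = "") -> None:
    """Orthogonal mid-slice montage with Max/Threshold annotations (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = diff.data
    centers = [s // 2 for s in data.shape]
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    for ax, (axis, c) in zip(axes, enumerate(centers)):
        sl = np.take(data, c, axis=axis)
        im = ax.imshow(sl.T, origin="lower", cmap="hot")
        ax.set_title(f"axis {axis} slice {c}", fontsize=8)
        ax.axis("off")
    fig.colorbar(im, ax=axes, shrink=0.8,
                 label=f"Max {data.max():.3g} / Threshold {diff.threshold:.3g}"
                 if diff.threshold is not None else "activation difference")
    if title:
        fig.suptitle(title, fontsize=10)
    fig.savefig(path, dpi=110)
    plt.close(fig)
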