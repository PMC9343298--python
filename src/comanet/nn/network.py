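"""A sequential container with parameter accounting and activation taps."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        # set by the architecture builder: indices of the post-BN+ELU
        # output of each convolutional block, in network order
        self.conv_tap_indices: list[int] = []

    def forward(self, x: np.ndarray, training: bool = False,
                collect: list[int] | None = None):
        """Run the cascade; optionally collect intermediate outputs.

        Returns the final output, or ``(output, {index: activation})``
        when ``collect`` is given.
        """
        taps: dict[int, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, training=training)
            if collect is not None and i in collect:
                taps[i] = x
        if collect is not None:
            return x, taps
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for layer in self.layers:
            for name, arr in layer.params.items():
                yield layer, name, arr

    def parameter_counts(self) -> tuple[int, int]:
        """(total, trainable) as a framework would report them.

        Trainable covers kernels, biases and BN scale/shift; the total
        additionally counts BN running statistics.
        """
        trainable = sum(arr.size for _, _, arr in self.parameters())
        state = sum(arr.size for layer in self.layers
                    for arr in layer.state_arrays().values())
        return trainable + state, trainable

    def l2_penalty_and_grads(self, factor: float) -> float:
        """Add Keras-convention L2 (factor * sum(W^2)) to kernel grads; return the penalty."""
        if factor == 0.0:
            return 0.0
        penalty = 0.0
        for layer in self.layers:
            for name in layer.kernel_names:
                w = layer.params[name]
                penalty += factor * float(np.sum(w.astype(np.float64) ** 2))
                layer.grads[name] += 2.0 * factor * w
        return penalty

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"layer{i}.{name}"] = arr
            for name, arr in layer.state_arrays().items():
                out[f"layer{i}.{name}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"layer{i}.{name}"])
            for name in layer.state_arrays():
                setattr(layer, name, np.asarray(state[f"layer{i}.{name}"]))
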