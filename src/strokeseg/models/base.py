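"""Shared machinery for the executable segmentation networks."""

from __future__ import annotations

import numpy as np

from ..nn import Layer, Param


class Network:
    """A named registry of layers with state (de)serialisation and batched
    prediction. Subclasses wire the layers explicitly in forward/backward."""

    def __init__(self, seed: int | None = 0):
        self.layers: dict[str, Layer] = {}
        self.rng = np.random.default_rng(seed)

    def _register(self, name: str, layer: Layer) -> Layer:
        layer.name = name
        for p in layer.params():  # re-key params under the registered path
            p.name = f"{name}.{p.name.rsplit('.', 1)[-1]}"
        self.layers[name] = layer
        return layer

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers.values():
            out.extend(layer.params())
        return out

    def conv_kernel_names(self) -> set[str]:
        """Names of convolution kernels — the weight set the L2 penalty covers."""
        return {p.name for p in self.params() if p.name.endswith(".w")}

    def n_trainable(self) -> int:
        return sum(layer.n_trainable() for layer in self.layers.values())

    def n_non_trainable(self) -> int:
        return sum(layer.n_non_trainable() for layer in self.layers.values())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Forward in inference mode, batched over the leading axis."""
        outs = [self.forward(x[i:i + batch_size], training=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, layer in self.layers.items():
            for p in layer.params():
                state[p.name] = p.value.copy()
            for i, arr in enumerate(layer.non_trainable_arrays()):
                state[f"{name}.stat{i}"] = arr.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers.items():
            for p in layer.params():
                p.value[:] = state[p.name]
            for i, arr in enumerate(layer.non_trainable_arrays()):
                arr[:] = state[f"{name}.stat{i}"]

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))
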