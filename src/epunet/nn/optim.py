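"""First-order optimizers for the layer stack."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD"]


class SGD:
    """Stochastic gradient descent with classical momentum.

    Parameters are addressed by the flat (path, layer, key) triples yielded
    by ``Sequential.named_params`` plus any extra standalone arrays (the
    ensemble bias) registered via ``add_param``.
    """

    def __init__(self, lr: float = 1e-2, momentum: float = 0.9):
        self.lr = lr
        self.momentum = momentum
        self._velocity: dict[str, np.ndarray] = {}
        self._entries: list[tuple[str, object, str]] = []

    def register(self, named_params) -> None:
        for path, layer, key in named_params:
            self._entries.append((path, layer, key))
            self._velocity[path] = np.zeros_like(layer.params[key])

    def step(self) -> None:
        for path, layer, key in self._entries:
            g = layer.grads.get(key)
            if g is None:
                continue
            v = self._velocity[path]
            v *= self.momentum
            v -= self.lr * g.astype(v.dtype)
            layer.params[key] += v
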