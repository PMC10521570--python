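"""Adam optimiser over a flat parameter list."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam"]


class Adam:
    """Adam with the usual bias-corrected first/second moment estimates.

    ``l2`` adds a coupled quadratic penalty ``l2 * sum(w**2)`` whose gradient
    (``2*l2*w``) is applied only to parameters whose names appear in
    ``l2_param_names`` — the segmentation models pass their convolution
    kernels and leave biases and normalisation parameters unpenalised.
    """

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7,
                 l2: float = 0.0, l2_param_names: set[str] | None = None):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.l2 = l2
        self.l2_param_names = l2_param_names or set()
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def penalty(self) -> float:
        """Current value of the L2 term added to the objective."""
        if self.l2 == 0.0:
            return 0.0
        return self.l2 * float(sum(np.sum(p.value.astype(np.float64) ** 2)
                                   for p in self.params if p.name in self.l2_param_names))

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if self.l2 and p.name in self.l2_param_names:
                g = g + 2.0 * self.l2 * p.value
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / bc1
            vhat = self._v[i] / bc2
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[:] = 0.0
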