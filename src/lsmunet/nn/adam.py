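"""Adam optimizer over nested-dict parameter trees."""

from __future__ import annotations

from autograd.misc import flatten


class Adam:
    """Standard Adam (Kingma & Ba) on a flattened parameter vector."""

    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        flat, self._unflatten = flatten(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = 0.0 * flat
        self.v = 0.0 * flat
        self.t = 0

    def step(self, params, grads):
        """Apply one update; returns the new parameter tree."""
        flat, unflatten = flatten(params)
        gflat, _ = flatten(grads)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * gflat
        self.v = self.beta2 * self.v + (1 - self.beta2) * gflat**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return unflatten(flat - self.lr * mhat / (vhat**0.5 + self.eps))
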