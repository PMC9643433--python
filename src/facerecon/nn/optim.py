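"""Parameter-update rules operating on a layer container's params_and_grads()."""

from __future__ import annotations

import numpy as np


class SGD:
    def __init__(self, lr=0.001, momentum=0.0):
        self.lr = lr
        self.momentum = momentum
        self._velocity = {}

    def step(self, container):
        for name, v, g, wd in container.params_and_grads():
            update = g + wd * v if wd else g
            if self.momentum:
                vel = self._velocity.setdefault(name, np.zeros_like(v))
                vel *= self.momentum
                vel -= self.lr * update
                v += vel
            else:
                v -= self.lr * update


class Adam:
    def __init__(self, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = {}
        self._v = {}
        self._t = 0

    def step(self, container):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for name, v, g, wd in container.params_and_grads():
            grad = g + wd * v if wd else g
            m = self._m.setdefault(name, np.zeros_like(v))
            s = self._v.setdefault(name, np.zeros_like(v))
            m *= b1
            m += (1 - b1) * grad
            s *= b2
            s += (1 - b2) * grad**2
            mhat = m / (1 - b1**self._t)
            shat = s / (1 - b2**self._t)
            v -= self.lr * mhat / (np.sqrt(shat) + self.eps)
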