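"""Adam/AdamW and the warm-up + cosine-decay learning-rate schedule."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with optional L2-through-gradient; decoupled decay in AdamW."""

    decoupled = False

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        if lr is None:
            lr = self.lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.value
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and self.decoupled:
                update = update + self.weight_decay * p.value
            p.value -= np.float32(lr) * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class AdamW(Adam):
    decoupled = True


def warmup_cosine_lr(step: int, total_steps: int, warmup_steps: int,
                     lr_max: float) -> float:
    """Linear warm-up from 0 to lr_max over ``warmup_steps``, then cosine
    decay to 0 at ``total_steps``.  lr(0) = 0, lr(warmup_steps) = lr_max."""
    if warmup_steps > 0 and step < warmup_steps:
        return lr_max * step / warmup_steps
    if total_steps <= warmup_steps:
        return lr_max
    frac = (step - warmup_steps) / (total_steps - warmup_steps)
    frac = min(max(frac, 0.0), 1.0)
    return lr_max * 0.5 * (1.0 + np.cos(np.pi * frac))
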