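"""AdamW with decoupled weight decay and per-group learning rates."""

from __future__ import annotations

import numpy as np


class AdamW:
    def __init__(self, param_groups, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        # accept a flat iterable of parameters or a list of {"params", "lr"} dicts
        param_groups = list(param_groups)
        if param_groups and not isinstance(param_groups[0], dict):
            param_groups = [{"params": param_groups}]
        self.groups = []
        for g in param_groups:
            self.groups.append({
                "params": list(g["params"]),
                "lr": g.get("lr", lr),
                "betas": g.get("betas", betas),
                "eps": g.get("eps", eps),
                "weight_decay": g.get("weight_decay", weight_decay),
            })
        self._state = {}
        self._step = 0

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self._step += 1
        t = self._step
        for g in self.groups:
            beta1, beta2 = g["betas"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                state = self._state.setdefault(id(p), {
                    "m": np.zeros_like(p.data), "v": np.zeros_like(p.data)})
                m, v = state["m"], state["v"]
                m *= beta1
                m += (1 - beta1) * p.grad
                v *= beta2
                v += (1 - beta2) * p.grad ** 2
                m_hat = m / (1 - beta1 ** t)
                v_hat = v / (1 - beta2 ** t)
                p.data = p.data - g["lr"] * (
                    m_hat / (np.sqrt(v_hat) + g["eps"]) + g["weight_decay"] * p.data)


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad = p.grad * scale
    return total
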