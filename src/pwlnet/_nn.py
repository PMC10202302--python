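"""Minimal dense-network machinery for the reallocation function.

Two topologies are supported. ``plain`` is a standard MLP. ``unified`` is
"horizontally shallow and vertically deep": every hidden block receives the
raw input through a direct connection and every block contributes additively
to the output aggregation, so the shortest input-to-output path is two hops
regardless of depth. Depth counts total layers including the output layer,
so ``depth=2`` means one hidden block.

Everything is float64 numpy with hand-written backprop; training is
full-batch, hence bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _act(z: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (activation, elementwise derivative)."""
    if kind == "tanh":
        a = np.tanh(z)
        return a, 1.0 - a * a
    if kind == "relu":
        mask = z > 0
        return np.where(mask, z, 0.0), mask.astype(float)
    if kind == "selu":
        pos = z > 0
        ez = np.exp(np.minimum(z, 0.0))
        a = _SELU_LAMBDA * np.where(pos, z, _SELU_ALPHA * (ez - 1.0))
        da = _SELU_LAMBDA * np.where(pos, 1.0, _SELU_ALPHA * ez)
        return a, da
    raise ValueError(f"unknown activation {kind!r}")


class EtaNetwork:
    """Dense network mapping R^d_in -> R^d_out."""

    def __init__(
        self,
        d_in: int,
        d_out: int,
        depth: int,
        width: int,
        topology: str = "unified",
        activation: str = "tanh",
        rng: np.random.Generator | None = None,
        out_init: str = "unit",
    ) -> None:
        if depth < 2:
            raise ValueError(f"network depth must be >= 2, got {depth}")
        if topology not in ("unified", "plain"):
            raise ValueError(f"unknown topology {topology!r}")
        self.d_in, self.d_out = d_in, d_out
        self.depth, self.width = depth, width
        self.topology, self.activation = topology, activation
        self.n_hidden = depth - 1
        if rng is None:
            rng = np.random.default_rng(0)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(rng, out_init)

    def _glorot(self, rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
        fan_out, fan_in = shape
        return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=shape)

    def _init_params(self, rng: np.random.Generator, out_init: str) -> None:
        p = self.params
        w, d_in, d_out = self.width, self.d_in, self.d_out
        p["W1"] = self._glorot(rng, (w, d_in))
        p["b1"] = np.zeros(w)
        for l in range(2, self.n_hidden + 1):
            p[f"W{l}"] = self._glorot(rng, (w, w))
            p[f"b{l}"] = np.zeros(w)
            if self.topology == "unified":
                p[f"U{l}"] = self._glorot(rng, (w, d_in))
        if self.topology == "unified":
            for l in range(1, self.n_hidden + 1):
                p[f"A{l}"] = self._glorot(rng, (d_out, w))
            p["B"] = self._glorot(rng, (d_out, d_in))
            p["c"] = np.zeros(d_out)
            if out_init in ("unit", "zero"):
                for l in range(1, self.n_hidden + 1):
                    p[f"A{l}"][:] = 0.0
                p["B"][:] = 0.0
                p["c"][:] = 1.0 if out_init == "unit" else 0.0
        else:
            p["Wout"] = self._glorot(rng, (d_out, w))
            p["bout"] = np.zeros(d_out)
            if out_init in ("unit", "zero"):
                p["Wout"][:] = 0.0
                p["bout"][:] = 1.0 if out_init == "unit" else 0.0

    def forward(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Forward pass; pass a dict as ``cache`` to enable ``backward``."""
        p = self.params
        h_list, da_list = [], []
        h = None
        for l in range(1, self.n_hidden + 1):
            z = (X if l == 1 else h) @ p[f"W{l}"].T + p[f"b{l}"]
            if self.topology == "unified" and l >= 2:
                z = z + X @ p[f"U{l}"].T
            h, da = _act(z, self.activation)
            h_list.append(h)
            da_list.append(da)
        if self.topology == "unified":
            out = X @ p["B"].T + p["c"]
            for l in range(1, self.n_hidden + 1):
                out = out + h_list[l - 1] @ p[f"A{l}"].T
        else:
            out = h @ p["Wout"].T + p["bout"]
        if cache is not None:
            cache["X"], cache["h"], cache["da"] = X, h_list, da_list
        return out

    def backward(self, cache: dict, d_out: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt all params, given dL/d(output)."""
        p = self.params
        X, h_list, da_list = cache["X"], cache["h"], cache["da"]
        g: dict[str, np.ndarray] = {}
        # dL/dh_l accumulated from the output aggregation (unified) or chain
        dh = [np.zeros_like(h) for h in h_list]
        if self.topology == "unified":
            g["B"] = d_out.T @ X
            g["c"] = d_out.sum(axis=0)
            for l in range(1, self.n_hidden + 1):
                g[f"A{l}"] = d_out.T @ h_list[l - 1]
                dh[l - 1] += d_out @ p[f"A{l}"]
        else:
            g["Wout"] = d_out.T @ h_list[-1]
            g["bout"] = d_out.sum(axis=0)
            dh[-1] += d_out @ p["Wout"]
        for l in range(self.n_hidden, 0, -1):
            dz = dh[l - 1] * da_list[l - 1]
            prev = X if l == 1 else h_list[l - 2]
            g[f"W{l}"] = dz.T @ prev
            g[f"b{l}"] = dz.sum(axis=0)
            if l >= 2:
                dh[l - 2] += dz @ p[f"W{l}"]
            if self.topology == "unified" and l >= 2:
                g[f"U{l}"] = dz.T @ X
        return g

    def state(self) -> dict:
        return {k: v.tolist() for k, v in self.params.items()}

    def load_state(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = np.asarray(v, dtype=float)


class Adam:
    """Plain Adam; weight decay is applied only to weight matrices
    (parameter names not starting with 'b' or 'c')."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.05,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            if self.wd and not k.startswith(("b", "c")):
                g = g + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
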