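"""Invertible flow layers with hand-written backpropagation.

Three layer kinds make up the flow:

* ``ConditionalAffine`` — an element-wise affine map whose scale and shift
  are produced by a small network of the *condition vector only*:
  u = exp(a') * x + b with a' = alpha * psi(a) and (a, b) = SPLIT(s(c)).
  This is the only layer with a non-zero log-Jacobian, sum(a').
* ``GinCoupling`` — a conditional coupling layer whose active half is
  scaled/shifted by subnetworks of (passive half, condition).  The raw
  per-coordinate log-scales tanh(s(.)) are re-centred to sum exactly to
  zero before exponentiation, so |det J| = 1 (the incompressible-flow
  constraint) and the layer contributes nothing to the log-likelihood's
  volume term.
* ``GinBlock`` — two couplings with swapped active halves, then a fixed
  permutation, then a trainable global offset.

All parameter and gradient arrays live in per-layer dicts and are updated
in place, which keeps the optimizer a plain loop over (param, grad) pairs.
The batch convention is rows = samples: x has shape (n, d), c has (n, d_c).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["MLP", "ConditionalAffine", "GinCoupling", "GinBlock"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * phi


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


_ACTS = {"gelu": (_gelu, _gelu_grad), "relu": (_relu, _relu_grad)}


class MLP:
    """linear -> activation -> linear, with manual forward/backward.

    The final layer starts at zero so every flow layer begins as an
    identity map — the standard stable initialization for flows.
    """

    def __init__(self, d_in: int, d_hidden: int, d_out: int, activation: str,
                 rng: np.random.Generator) -> None:
        self.act, self.act_grad = _ACTS[activation]
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_hidden)),
            "b1": np.zeros(d_hidden),
            "W2": np.zeros((d_hidden, d_out)),
            "b2": np.zeros(d_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        h = x @ self.params["W1"] + self.params["b1"]
        g = self.act(h)
        out = g @ self.params["W2"] + self.params["b2"]
        return out, (x, h, g)

    def backward(self, dout: np.ndarray, cache: tuple) -> np.ndarray:
        x, h, g = cache
        self.grads["W2"] += g.T @ dout
        self.grads["b2"] += dout.sum(axis=0)
        dg = dout @ self.params["W2"].T
        dh = dg * self.act_grad(h)
        self.grads["W1"] += x.T @ dh
        self.grads["b1"] += dh.sum(axis=0)
        return dh @ self.params["W1"].T


class _Layer:
    """Shared parameter bookkeeping."""

    def named_parameters(self):
        for sub_name, sub in self._subnets():
            if isinstance(sub, _Layer):
                for n, p, g in sub.named_parameters():
                    yield f"{sub_name}.{n}", p, g
            else:  # a bare MLP
                for k in sub.params:
                    yield f"{sub_name}.{k}", sub.params[k], sub.grads[k]
        for k in getattr(self, "params", {}):
            yield k, self.params[k], self.grads[k]

    def zero_grads(self) -> None:
        for _, _, g in self.named_parameters():
            g[...] = 0.0

    def _subnets(self):
        return ()


class ConditionalAffine(_Layer):
    """Condition-driven element-wise affine transform (the volume carrier)."""

    def __init__(self, d: int, d_c: int, hidden: int, alpha: float,
                 rng: np.random.Generator) -> None:
        self.d = d
        self.alpha = float(alpha)
        self.net = MLP(d_c, hidden, 2 * d, "gelu", rng)

    def _subnets(self):
        return (("net", self.net),)

    def _coeffs(self, c: np.ndarray):
        out, net_cache = self.net.forward(c)
        a, b = out[:, : self.d], out[:, self.d:]
        ta = np.tanh(a)
        ap = self.alpha * ta
        return a, b, ta, ap, net_cache

    def forward(self, x: np.ndarray, c: np.ndarray):
        a, b, ta, ap, net_cache = self._coeffs(c)
        u = np.exp(ap) * x + b
        logdet = ap.sum(axis=1)
        cache = (x, ta, ap, net_cache)
        return u, logdet, cache

    def inverse(self, u: np.ndarray, c: np.ndarray) -> np.ndarray:
        _, b, _, ap, _ = self._coeffs(c)
        return (u - b) * np.exp(-ap)

    def backward(self, du: np.ndarray, dlogdet: np.ndarray, cache: tuple
                 ) -> np.ndarray:
        x, ta, ap, net_cache = cache
        eap = np.exp(ap)
        dap = du * x * eap + dlogdet[:, None]
        da = dap * self.alpha * (1.0 - ta * ta)
        dout = np.concatenate([da, du], axis=1)
        self.net.backward(dout, net_cache)
        return du * eap


class GinCoupling(_Layer):
    """Volume-preserving conditional coupling layer.

    ``active_idx`` coordinates are transformed conditionally on the
    remaining (passive) coordinates and the condition vector; the raw
    log-scales are mean-centred so they sum to zero exactly, hence the
    Jacobian determinant is exactly 1.
    """

    def __init__(self, d: int, d_c: int, hidden: int, active_first: bool,
                 rng: np.random.Generator) -> None:
        self.d = d
        d1 = (d + 1) // 2
        if active_first:
            self.active = np.arange(0, d1)
            self.passive = np.arange(d1, d)
        else:
            self.active = np.arange(d - d1, d)
            self.passive = np.arange(0, d - d1)
        n_act, n_pas = len(self.active), len(self.passive)
        self.s_net = MLP(n_pas + d_c, hidden, n_act, "relu", rng)
        self.t_net = MLP(n_pas + d_c, hidden, n_act, "relu", rng)

    def _subnets(self):
        return (("s", self.s_net), ("t", self.t_net))

    def _scales(self, x_pas: np.ndarray, c: np.ndarray):
        m = np.concatenate([x_pas, c], axis=1)
        s_raw, s_cache = self.s_net.forward(m)
        r = np.tanh(s_raw)
        rc = r - r.mean(axis=1, keepdims=True)  # zero-sum log-scales
        t_out, t_cache = self.t_net.forward(m)
        return m, r, rc, t_out, s_cache, t_cache

    def forward(self, x: np.ndarray, c: np.ndarray):
        x_act, x_pas = x[:, self.active], x[:, self.passive]
        m, r, rc, t_out, s_cache, t_cache = self._scales(x_pas, c)
        u = x.copy()
        u[:, self.active] = x_act * np.exp(rc) + t_out
        cache = (x_act, r, rc, s_cache, t_cache)
        return u, cache

    def inverse(self, u: np.ndarray, c: np.ndarray) -> np.ndarray:
        u_pas = u[:, self.passive]  # passive half is untouched
        _, _, rc, t_out, _, _ = self._scales(u_pas, c)
        x = u.copy()
        x[:, self.active] = (u[:, self.active] - t_out) * np.exp(-rc)
        return x

    def backward(self, du: np.ndarray, cache: tuple) -> np.ndarray:
        x_act, r, rc, s_cache, t_cache = cache
        du_act = du[:, self.active]
        erc = np.exp(rc)
        dx = du.copy()
        drc = du_act * x_act * erc
        dr = drc - drc.mean(axis=1, keepdims=True)
        ds_raw = dr * (1.0 - r * r)
        dm_s = self.s_net.backward(ds_raw, s_cache)
        dm_t = self.t_net.backward(du_act, t_cache)
        dm = dm_s + dm_t
        n_pas = len(self.passive)
        dx[:, self.active] = du_act * erc
        dx[:, self.passive] = du[:, self.passive] + dm[:, :n_pas]
        return dx


class GinBlock(_Layer):
    """Two swapped-half couplings, a fixed permutation R, a global offset."""

    def __init__(self, d: int, d_c: int, hidden: int,
                 rng: np.random.Generator) -> None:
        self.d = d
        self.coupling1 = GinCoupling(d, d_c, hidden, active_first=True, rng=rng)
        self.coupling2 = GinCoupling(d, d_c, hidden, active_first=False, rng=rng)
        self.perm = rng.permutation(d)
        self.inv_perm = np.argsort(self.perm)
        self.params = {"t_global": np.zeros(d)}
        self.grads = {"t_global": np.zeros(d)}

    def _subnets(self):
        return (("c1", self.coupling1), ("c2", self.coupling2))

    def forward(self, x: np.ndarray, c: np.ndarray):
        u1, cache1 = self.coupling1.forward(x, c)
        u2, cache2 = self.coupling2.forward(u1, c)
        out = u2[:, self.perm] + self.params["t_global"]
        return out, (cache1, cache2)

    def inverse(self, u: np.ndarray, c: np.ndarray) -> np.ndarray:
        v = (u - self.params["t_global"])[:, self.inv_perm]
        v = self.coupling2.inverse(v, c)
        return self.coupling1.inverse(v, c)

    def backward(self, du: np.ndarray, cache: tuple) -> np.ndarray:
        cache1, cache2 = cache
        self.grads["t_global"] += du.sum(axis=0)
        dv = du[:, self.inv_perm]
        dv = self.coupling2.backward(dv, cache2)
        return self.coupling1.backward(dv, cache1)
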