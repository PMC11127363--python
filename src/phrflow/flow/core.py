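"""The conditional normalizing flow: configuration, the invertible map,
exact log-likelihood, gradients, and the anomaly score.

The flow maps a feature vector x (given condition c = (age, gender)) to a
latent z through a conditional affine layer followed by a stack of
volume-preserving coupling blocks.  The model density follows the change of
variables

    log p_X(x; theta, psi) = log p_Z(f_theta(x | c); psi) + log |det J_f(x)|

with p_Z a diagonal normal whose parameters psi may themselves be trained.
Only the affine layer contributes to the Jacobian term; every coupling
block has |det J| = 1 by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from ..exceptions import ConfigurationError, PhrflowError
from .layers import ConditionalAffine, GinBlock

__all__ = ["FlowConfig", "ConditionalFlow", "anomaly_score"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class FlowConfig:
    """Architecture hyperparameters.

    ``alpha`` is the soft-clamp constant multiplying the tanh-squashed
    affine log-scales (bounding them to (-alpha, alpha) keeps exp() tame);
    ``learnable_base`` frees the base-distribution parameters for the
    alternating-update training strategy.
    """

    d: int
    d_c: int = 2
    n_blocks: int = 8
    hidden_width: int = 64
    alpha: float = 1.9
    psi_activation: str = "tanh"
    learnable_base: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ConfigurationError("flow needs d >= 2")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.psi_activation != "tanh":
            raise ConfigurationError(
                "only the tanh soft clamp is implemented for psi"
            )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ConditionalFlow:
    """Invertible conditional map x <-> z with exact log-likelihood.

    Freshly constructed flows are exact identity maps up to the per-block
    permutations (all subnetwork output layers and offsets start at zero),
    so training starts from a well-conditioned point.
    """

    def __init__(self, config: FlowConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.affine = ConditionalAffine(
            config.d, config.d_c, config.hidden_width, config.alpha, rng
        )
        self.blocks = [
            GinBlock(config.d, config.d_c, config.hidden_width, rng)
            for _ in range(config.n_blocks)
        ]
        self.base_params = {
            "mu": np.zeros(config.d),
            "log_sigma": np.zeros(config.d),
        }
        self.base_grads = {k: np.zeros_like(v) for k, v in self.base_params.items()}

    # -- parameter access --------------------------------------------------

    def named_parameters(self, include_base: bool | None = None):
        """Yield (name, param, grad) triples; arrays are updated in place."""
        yield from ((f"affine.{n}", p, g)
                    for n, p, g in self.affine.named_parameters())
        for i, blk in enumerate(self.blocks):
            yield from ((f"block{i}.{n}", p, g)
                        for n, p, g in blk.named_parameters())
        if include_base is None:
            include_base = self.config.learnable_base
        if include_base:
            yield from self.base_named_parameters()

    def base_named_parameters(self):
        for k in self.base_params:
            yield f"base.{k}", self.base_params[k], self.base_grads[k]

    def zero_grads(self) -> None:
        self.affine.zero_grads()
        for blk in self.blocks:
            blk.zero_grads()
        for g in self.base_grads.values():
            g[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in
                self.named_parameters(include_base=True)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.named_parameters(include_base=True):
            p[...] = state[name]

    # -- the map -----------------------------------------------------------

    def _check(self, x: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        c = np.atleast_2d(np.asarray(c, dtype=float))
        if x.shape[1] != self.config.d:
            raise ConfigurationError(
                f"x has {x.shape[1]} columns, flow expects d={self.config.d}"
            )
        if c.shape[1] != self.config.d_c:
            raise ConfigurationError(
                f"c has {c.shape[1]} columns, flow expects d_c={self.config.d_c}"
            )
        if c.shape[0] != x.shape[0]:
            raise ConfigurationError("x and c row counts differ")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(c))):
            raise PhrflowError("non-finite values in flow input")
        return x, c

    def forward(self, x, c, with_cache: bool = False):
        """x -> (z, total log|det J|); blocks contribute zero log-det."""
        x, c = self._check(x, c)
        z, logdet, aff_cache = self.affine.forward(x, c)
        caches = [aff_cache]
        for blk in self.blocks:
            z, cache = blk.forward(z, c)
            caches.append(cache)
        if with_cache:
            return z, logdet, caches
        return z, logdet

    def inverse(self, z, c) -> np.ndarray:
        z, c = self._check(z, c)
        x = z
        for blk in reversed(self.blocks):
            x = blk.inverse(x, c)
        return self.affine.inverse(x, c)

    # -- densities ---------------------------------------------------------

    def _base_log_prob(self, z: np.ndarray) -> np.ndarray:
        mu = self.base_params["mu"]
        sigma = np.exp(self.base_params["log_sigma"])
        t = (z - mu) / sigma
        return (-0.5 * (t * t).sum(axis=1)
                - self.base_params["log_sigma"].sum()
                - 0.5 * self.config.d * _LOG_2PI)

    def log_likelihood(self, x, c) -> np.ndarray:
        """Exact per-sample log p_X(x | c)."""
        z, logdet = self.forward(x, c)
        return self._base_log_prob(z) + logdet

    def latent(self, x, c) -> np.ndarray:
        z, _ = self.forward(x, c)
        return z

    def sample(self, c, rng: np.random.Generator) -> np.ndarray:
        """Draw x | c by sampling the base distribution and inverting."""
        c = np.atleast_2d(np.asarray(c, dtype=float))
        mu = self.base_params["mu"]
        sigma = np.exp(self.base_params["log_sigma"])
        z = mu + sigma * rng.standard_normal((c.shape[0], self.config.d))
        return self.inverse(z, c)

    # -- training support --------------------------------------------------

    def nll_and_grads(self, x, c) -> float:
        """Mean negative log-likelihood of the batch; fills every gradient
        array (including the base-distribution gradients) in place."""
        self.zero_grads()
        z, logdet, caches = self.forward(x, c, with_cache=True)
        n = z.shape[0]
        mu = self.base_params["mu"]
        sigma = np.exp(self.base_params["log_sigma"])
        t = (z - mu) / sigma
        loss = float(np.mean(
            0.5 * (t * t).sum(axis=1)
            + self.base_params["log_sigma"].sum()
            + 0.5 * self.config.d * _LOG_2PI
            - logdet
        ))
        # d(loss)/dz and base-parameter gradients
        dz = (t / sigma) / n
        self.base_grads["mu"][...] = -(t / sigma).sum(axis=0) / n
        self.base_grads["log_sigma"][...] = (1.0 - t * t).sum(axis=0) / n
        dlogdet = np.full(n, -1.0 / n)
        for blk, cache in zip(reversed(self.blocks), reversed(caches[1:])):
            dz = blk.backward(dz, cache)
        self.affine.backward(dz, dlogdet, caches[0])
        return loss

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Named-array archive with a JSON config header."""
        header = json.dumps(
            {"config": asdict(self.config), "hash": self.config.config_hash()}
        )
        arrays = {name.replace(".", "__"): p
                  for name, p, _ in self.named_parameters(include_base=True)}
        perms = {f"perm__{i}": blk.perm for i, blk in enumerate(self.blocks)}
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays, **perms)

    @classmethod
    def load(cls, path) -> "ConditionalFlow":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            config = FlowConfig(**header["config"])
            if config.config_hash() != header["hash"]:
                raise ConfigurationError("flow checkpoint config hash mismatch")
            flow = cls(config)
            for name, p, _ in flow.named_parameters(include_base=True):
                p[...] = data[name.replace(".", "__")]
            for i, blk in enumerate(flow.blocks):
                blk.perm = data[f"perm__{i}"]
                blk.inv_perm = np.argsort(blk.perm)
        return flow


def anomaly_score(z) -> np.ndarray:
    """-exp(-||z||^2 / 2): negatively proportional to the base density,
    strictly increasing in ||z||, with range [-1, 0)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if not np.all(np.isfinite(z)):
        raise PhrflowError("non-finite latent values")
    return -np.exp(-0.5 * (z * z).sum(axis=1))
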