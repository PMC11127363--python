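"""Maximum-likelihood training of the conditional flow.

Training is strictly semi-supervised: the train table must contain zero
disease-affected rows, and this is asserted, not assumed.  The optimizer is
Adam with a cosine-annealing-with-warm-restarts learning-rate schedule (the
schedule is a closed-form function of the epoch index, so it can be checked
pointwise).  Optionally, the base-distribution parameters are trained by a
periodic separate update (the alternating-update strategy); this is off by
default because it can destabilize training on small tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..exceptions import ProtocolViolationError, TrainingDivergedError
from .core import ConditionalFlow, FlowConfig

__all__ = ["TrainConfig", "TrainHistory", "Adam", "cosine_warmup_lr",
           "nll_loss", "train"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 400
    batch_size: int = 64
    max_lr: float = 3e-3
    min_lr: float = 1e-5
    cycle_epochs: int = 50
    warmup_epochs: int = 5
    grad_clip: float = 2.0
    altub_enabled: bool = False
    altub_period: int = 4      # base-only update every k steps
    altub_lr: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_lr <= 0 or self.min_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.altub_period < 1:
            raise ValueError("altub_period must be >= 1")
        if not 0 < self.warmup_epochs < self.cycle_epochs:
            raise ValueError("need 0 < warmup_epochs < cycle_epochs")


@dataclass
class TrainHistory:
    train_nll: list[float] = field(default_factory=list)
    val_nll: list[float] | None = None
    lr_trace: list[float] = field(default_factory=list)
    seed: int = 0
    best_epoch: int = -1


def cosine_warmup_lr(epoch: int, cycle_epochs: int, warmup_epochs: int,
                     min_lr: float, max_lr: float) -> float:
    """Closed-form cosine-annealing-with-warm-restarts schedule.

    Within each cycle of ``cycle_epochs`` epochs: linear warmup from
    ``min_lr`` to ``max_lr`` over the first ``warmup_epochs`` epochs, then
    cosine decay back to ``min_lr``; the cycle then restarts.
    """
    t = epoch % cycle_epochs
    if t < warmup_epochs:
        return min_lr + (max_lr - min_lr) * t / warmup_epochs
    frac = (t - warmup_epochs) / (cycle_epochs - warmup_epochs)
    return min_lr + 0.5 * (max_lr - min_lr) * (1.0 + math.cos(math.pi * frac))


class Adam:
    """In-place Adam over (name, param, grad) triples."""

    def __init__(self, triples, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.triples = list(triples)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {name: np.zeros_like(p) for name, p, _ in self.triples}
        self.v = {name: np.zeros_like(p) for name, p, _ in self.triples}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for name, p, g in self.triples:
            m = self.m[name]
            v = self.v[name]
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def nll_loss(x, c, flow: ConditionalFlow) -> float:
    """Mean negative log-likelihood of a batch."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("empty batch")
    loss = float(-np.mean(flow.log_likelihood(x, c)))
    if not np.isfinite(loss):
        raise TrainingDivergedError("non-finite negative log-likelihood")
    return loss


def _clip_grads(triples, max_norm: float) -> None:
    total = math.sqrt(sum(float((g * g).sum()) for _, _, g in triples))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for _, _, g in triples:
            g *= scale


def train(
    x_train: np.ndarray,
    c_train: np.ndarray,
    flow_config: FlowConfig,
    train_config: TrainConfig,
    labels: np.ndarray | None = None,
    x_val: np.ndarray | None = None,
    c_val: np.ndarray | None = None,
) -> tuple[ConditionalFlow, TrainHistory]:
    """Fit the flow by maximum likelihood on unaffected rows only.

    If ``labels`` is passed it must sum to zero — a train table containing
    any affected sample is a protocol violation, not a warning.  Returns
    the best state by train (or validation, when provided) NLL.
    """
    x_train = np.atleast_2d(np.asarray(x_train, dtype=float))
    c_train = np.atleast_2d(np.asarray(c_train, dtype=float))
    if labels is not None:
        labels = np.asarray(labels, dtype=float)
        n_pos = int(np.nansum(labels))
        if n_pos != 0:
            raise ProtocolViolationError(
                f"{n_pos} affected sample(s) found in the training table; "
                "the flow must be trained on unaffected rows only"
            )
    n = x_train.shape[0]
    if n == 0:
        raise ValueError("empty training set")

    cfg = train_config
    flow = ConditionalFlow(flow_config)
    rng = np.random.default_rng(cfg.seed)

    triples = list(flow.named_parameters())  # honours learnable_base
    opt = Adam(triples, lr=cfg.max_lr)
    base_opt = None
    if cfg.altub_enabled:
        base_triples = list(flow.base_named_parameters())
        base_opt = Adam(base_triples, lr=cfg.altub_lr)

    history = TrainHistory(seed=cfg.seed, val_nll=None if x_val is None else [])
    best_nll = math.inf
    best_state = flow.state_dict()
    batch = max(1, min(cfg.batch_size, n))
    step = 0
    for epoch in range(cfg.epochs):
        lr = cosine_warmup_lr(epoch, cfg.cycle_epochs, cfg.warmup_epochs,
                              cfg.min_lr, cfg.max_lr)
        opt.lr = lr
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            loss = flow.nll_and_grads(x_train[idx], c_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {step}"
                )
            _clip_grads(triples, cfg.grad_clip)
            opt.step()
            step += 1
            if base_opt is not None and step % cfg.altub_period == 0:
                # periodic base-distribution-only refinement
                flow.nll_and_grads(x_train[idx], c_train[idx])
                base_opt.step()
            epoch_losses.append(loss)
        mean_nll = float(np.mean(epoch_losses))
        history.train_nll.append(mean_nll)
        history.lr_trace.append(lr)
        monitor = mean_nll
        if x_val is not None:
            v = nll_loss(x_val, c_val, flow)
            history.val_nll.append(v)
            monitor = v
        if monitor < best_nll:
            best_nll = monitor
            best_state = flow.state_dict()
            history.best_epoch = epoch
    flow.load_state_dict(best_state)
    return flow, history
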