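"""Model/Results facade over the conditional flow.

``ConditionalFlowModel`` holds the (already preprocessed) feature matrix
and the condition matrix; ``fit`` runs maximum-likelihood training on the
unaffected rows and returns a ``ConditionalFlowResults`` carrying the
fitted flow, the training history, per-sample likelihood and anomaly-score
methods, and a text summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .flow.core import ConditionalFlow, FlowConfig, anomaly_score
from .flow.training import TrainConfig, TrainHistory, train

__all__ = ["ConditionalFlowModel", "ConditionalFlowResults"]


class ConditionalFlowModel:
    """Conditional-flow density model of unaffected tabular health data.

    Parameters
    ----------
    endog : (n, d) array or DataFrame
        Preprocessed feature matrix (no condition columns, no labels).
    cond : (n, d_c) array or DataFrame
        Condition matrix, by convention (age, gender).
    labels : optional (n,) binary vector
        If given, only label-0 rows are used for fitting, and passing a
        table that is *all* affected is an error.
    """

    def __init__(self, endog, cond, labels=None, feature_names=None) -> None:
        if isinstance(endog, pd.DataFrame):
            feature_names = feature_names or list(endog.columns)
        self.endog = np.atleast_2d(np.asarray(endog, dtype=float))
        self.cond = np.atleast_2d(np.asarray(cond, dtype=float))
        if self.endog.shape[0] != self.cond.shape[0]:
            raise ConfigurationError("endog and cond row counts differ")
        self.labels = None if labels is None else np.asarray(labels, dtype=float)
        self.feature_names = feature_names or [
            f"x{i}" for i in range(self.endog.shape[1])
        ]

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        condition_columns: tuple[str, str] = ("age", "gender"),
        label_column: str | None = None,
    ) -> "ConditionalFlowModel":
        cond = list(condition_columns)
        missing = [c for c in cond if c not in data.columns]
        if missing:
            raise ConfigurationError(f"missing condition columns: {missing}")
        labels = None
        drop = cond.copy()
        if label_column is not None:
            if label_column not in data.columns:
                raise ConfigurationError(f"missing label column {label_column!r}")
            labels = data[label_column].to_numpy(dtype=float)
            drop.append(label_column)
        feats = data.drop(columns=drop)
        return cls(feats, data[cond], labels=labels,
                   feature_names=list(feats.columns))

    def fit(
        self,
        flow_config: FlowConfig | None = None,
        train_config: TrainConfig | None = None,
        val_fraction: float = 0.15,
        **train_kwargs,
    ) -> "ConditionalFlowResults":
        """Maximum-likelihood fit on the unaffected rows.

        ``val_fraction`` of the unaffected rows is held out for best-state
        selection by validation NLL — density models of small tables
        overfit quickly, so early selection matters.  Set it to 0 to
        select on train NLL instead.
        """
        d = self.endog.shape[1]
        if flow_config is None:
            flow_config = FlowConfig(d=d, d_c=self.cond.shape[1])
        if train_config is None:
            train_config = TrainConfig(**train_kwargs)
        elif train_kwargs:
            raise ConfigurationError(
                "pass either train_config or keyword overrides, not both"
            )
        x, c = self.endog, self.cond
        labels = self.labels
        if labels is not None:
            keep = ~(labels == 1)
            x, c = x[keep], c[keep]
            labels = labels[keep]
        x_val = c_val = None
        if val_fraction and len(x) >= 20:
            rng = np.random.default_rng(train_config.seed)
            perm = rng.permutation(len(x))
            n_val = max(1, int(round(val_fraction * len(x))))
            val, tr = perm[:n_val], perm[n_val:]
            x_val, c_val = x[val], c[val]
            x, c = x[tr], c[tr]
            labels = None if labels is None else labels[tr]
        flow, history = train(x, c, flow_config, train_config, labels=labels,
                              x_val=x_val, c_val=c_val)
        return ConditionalFlowResults(self, flow, history, flow_config,
                                      train_config)


class ConditionalFlowResults:
    """Fitted conditional flow plus training history and diagnostics."""

    def __init__(self, model: ConditionalFlowModel, flow: ConditionalFlow,
                 history: TrainHistory, flow_config: FlowConfig,
                 train_config: TrainConfig) -> None:
        self.model = model
        self.flow = flow
        self.history = history
        self.flow_config = flow_config
        self.train_config = train_config

    # -- inference ---------------------------------------------------------

    def log_likelihood(self, X=None, C=None) -> np.ndarray:
        if X is None:
            X, C = self.model.endog, self.model.cond
        return self.flow.log_likelihood(X, C)

    def latent(self, X=None, C=None) -> np.ndarray:
        if X is None:
            X, C = self.model.endog, self.model.cond
        return self.flow.latent(X, C)

    def anomaly_scores(self, X=None, C=None) -> np.ndarray:
        """Higher = more anomalous; range [-1, 0)."""
        return anomaly_score(self.latent(X, C))

    def score(self, X, C) -> np.ndarray:
        """Scorer-protocol alias for :meth:`anomaly_scores`."""
        return self.anomaly_scores(X, C)

    def simulate(self, C=None, seed: int = 0) -> np.ndarray:
        """Sample synthetic unaffected-like rows for the given conditions."""
        if C is None:
            C = self.model.cond
        return self.flow.sample(C, np.random.default_rng(seed))

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        h = self.history
        fc = self.flow_config
        n_params = sum(p.size for _, p, _ in
                       self.flow.named_parameters(include_base=True))
        lines = [
            "Conditional Normalizing Flow Results",
            "=" * 52,
            f"{'No. observations (fit):':<32}{self.model.endog.shape[0]:>20}",
            f"{'Feature dimension d:':<32}{fc.d:>20}",
            f"{'Condition dimension d_c:':<32}{fc.d_c:>20}",
            f"{'Coupling blocks:':<32}{fc.n_blocks:>20}",
            f"{'Subnet width:':<32}{fc.hidden_width:>20}",
            f"{'Soft-clamp alpha:':<32}{fc.alpha:>20.3f}",
            f"{'Learnable base:':<32}{str(fc.learnable_base):>20}",
            f"{'Parameters:':<32}{n_params:>20}",
            f"{'Epochs run:':<32}{len(h.train_nll):>20}",
            f"{'Best epoch:':<32}{h.best_epoch:>20}",
            f"{'Initial train NLL:':<32}{h.train_nll[0]:>20.4f}",
            f"{'Final train NLL:':<32}{h.train_nll[-1]:>20.4f}",
            f"{'Best monitored NLL:':<32}"
            f"{min(h.val_nll or h.train_nll):>20.4f}",
            "=" * 52,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.flow.save(path)

    def plot_history(self, ax=None):
        """NLL learning curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history.train_nll, label="train NLL")
        if self.history.val_nll:
            ax.plot(self.history.val_nll, label="validation NLL")
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean negative log-likelihood")
        ax.legend()
        return ax
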