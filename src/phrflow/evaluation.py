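"""Base-rate-preserving evaluation machinery.

Semi-supervised anomaly detectors are trained on unaffected rows only, so
the test protocol must (a) never leak affected rows into training and (b)
keep every test fold's positive proportion close to the cohort base rate —
otherwise AUPRC values are incomparable across folds.  The protocol here:
unaffected rows are split 8:2 into a train pool and a shared test pool;
affected rows are partitioned into five near-equal subsets; each test fold
is the shared unaffected pool plus one affected subset.  Metrics are
averaged over folds, experiments are repeated with re-drawn seeds, and
means are reported with normal-approximation 95% confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, PhrflowError
from .metrics import auprc, auroc

__all__ = [
    "SplitPlan",
    "RepetitionSummary",
    "SweepResult",
    "make_split_plan",
    "evaluate_model",
    "undersample_positives",
    "run_repetitions",
    "compare_models",
    "diagnostics",
]


@dataclass
class SplitPlan:
    """Index sets implementing the semi-supervised protocol."""

    train_idx: np.ndarray           # unaffected only
    test_pool_idx: np.ndarray       # unaffected test pool, shared by folds
    affected_subsets: list[np.ndarray]
    seed: int
    base_rate: float                # cohort base rate among labelled rows
    validation_subset: np.ndarray | None = None

    @property
    def n_folds(self) -> int:
        return len(self.affected_subsets)

    def fold_indices(self, k: int) -> np.ndarray:
        return np.concatenate([self.test_pool_idx, self.affected_subsets[k]])

    def fold_base_rate(self, k: int) -> float:
        n_pos = len(self.affected_subsets[k])
        return n_pos / (n_pos + len(self.test_pool_idx))


def make_split_plan(
    labels,
    seed: int,
    ratio: float = 0.8,
    n_folds: int = 5,
    reserve_validation_subset: bool = False,
    base_rate_rel_tol: float = 0.30,
) -> SplitPlan:
    """Build the unaffected-8:2 / affected-five-subset split plan.

    Rows with missing labels are excluded.  Raises if fewer affected rows
    than folds are available (pass a smaller ``n_folds`` to override) or if
    some fold's positive proportion would be off the cohort base rate by
    more than the configured relative tolerance.
    """
    labels = np.asarray(labels, dtype=float).ravel()
    observed = np.flatnonzero(~np.isnan(labels))
    pos = observed[labels[observed] == 1]
    neg = observed[labels[observed] == 0]
    if len(pos) < n_folds:
        raise ConfigurationError(
            f"only {len(pos)} affected samples for {n_folds} folds; "
            "configure fewer folds"
        )
    if len(neg) == 0:
        raise ConfigurationError("no unaffected samples")
    base_rate = len(pos) / len(observed)

    rng = np.random.default_rng(seed)
    neg_perm = rng.permutation(neg)
    n_train = int(round(ratio * len(neg)))
    train_idx = np.sort(neg_perm[:n_train])
    test_pool = np.sort(neg_perm[n_train:])

    pos_perm = rng.permutation(pos)
    n_subsets = n_folds + (1 if reserve_validation_subset else 0)
    if len(pos) < n_subsets:
        raise ConfigurationError(
            f"need at least {n_subsets} affected samples "
            "(validation subset reserved)"
        )
    subsets = [np.sort(s) for s in np.array_split(pos_perm, n_subsets)]
    validation = subsets.pop() if reserve_validation_subset else None

    plan = SplitPlan(train_idx, test_pool, subsets, seed, base_rate,
                     validation_subset=validation)
    for k in range(plan.n_folds):
        fr = plan.fold_base_rate(k)
        if abs(fr - base_rate) > base_rate_rel_tol * base_rate:
            raise ConfigurationError(
                f"fold {k} base rate {fr:.4f} deviates more than "
                f"{base_rate_rel_tol:.0%} from cohort base rate {base_rate:.4f}"
            )
    return plan


def evaluate_model(scorer, plan: SplitPlan, X, C, y) -> dict:
    """Score every fold and average AUROC/AUPRC across folds.

    ``scorer`` must expose ``score(X, C) -> array`` (higher = more
    positive/anomalous) and must have been fitted on the plan's train rows
    only — that contract is the caller's responsibility.
    """
    X = np.asarray(X, dtype=float)
    C = None if C is None else np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float)
    per_fold = []
    for k in range(plan.n_folds):
        idx = plan.fold_indices(k)
        scores = np.asarray(
            scorer.score(X[idx], None if C is None else C[idx]), dtype=float
        )
        if not np.all(np.isfinite(scores)):
            raise PhrflowError(f"scorer returned non-finite scores on fold {k}")
        fold_y = y[idx]
        per_fold.append(
            {"fold": k,
             "auroc": auroc(scores, fold_y),
             "auprc": auprc(scores, fold_y),
             "base_rate": plan.fold_base_rate(k)}
        )
    out = pd.DataFrame(per_fold)
    return {
        "auroc": float(out["auroc"].mean()),
        "auprc": float(out["auprc"].mean()),
        "per_fold": out,
    }


def undersample_positives(labels, fraction: float, seed: int) -> np.ndarray:
    """Positive undersampling: remove round(fraction * n_pos) affected rows
    uniformly at random; negatives (and missing labels) are untouched.
    Returns the retained row indices, sorted."""
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError("undersampling fraction must be in [0, 1)")
    labels = np.asarray(labels, dtype=float).ravel()
    pos = np.flatnonzero(labels == 1)
    n_remove = int(round(fraction * len(pos)))
    rng = np.random.default_rng(seed)
    removed = rng.choice(pos, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(len(labels)), removed)
    return keep


@dataclass
class RepetitionSummary:
    """Metric means with 95% normal-approximation confidence half-widths
    (1.96 * sd / sqrt(n)) over repeated seeded runs."""

    values: pd.DataFrame        # one row per repetition, one column per metric
    n_repetitions: int

    @property
    def means(self) -> pd.Series:
        return self.values.mean()

    @property
    def ci_half_widths(self) -> pd.Series:
        return 1.96 * self.values.std(ddof=1) / math.sqrt(self.n_repetitions)

    def __str__(self) -> str:
        parts = [
            f"{m}: {self.means[m]:.4f} +/- {self.ci_half_widths[m]:.4f}"
            for m in self.values.columns
        ]
        return f"[{self.n_repetitions} repetitions] " + ", ".join(parts)


def run_repetitions(experiment, n: int = 50, seed_base: int = 0
                    ) -> RepetitionSummary:
    """Run ``experiment(seed) -> {metric: value}`` for seeds
    seed_base .. seed_base + n - 1 and summarize."""
    if n < 2:
        raise ConfigurationError("need at least 2 repetitions for a CI")
    rows = []
    for i in range(n):
        out = experiment(seed_base + i)
        rows.append({"repetition": i, **out})
    values = pd.DataFrame(rows).set_index("repetition")
    return RepetitionSummary(values=values, n_repetitions=n)


@dataclass
class SweepResult:
    """Undersampling-fraction sweep: per (model, fraction) repetition
    summaries plus the realized base rate."""

    table: pd.DataFrame   # columns: model, fraction, repetition, auroc, auprc, base_rate

    def summarize(self) -> pd.DataFrame:
        g = self.table.groupby(["model", "fraction"])
        out = g.agg(
            auroc_mean=("auroc", "mean"),
            auprc_mean=("auprc", "mean"),
            auroc_sd=("auroc", "std"),
            auprc_sd=("auprc", "std"),
            base_rate=("base_rate", "mean"),
            n=("auprc", "size"),
        ).reset_index()
        out["auprc_ci95"] = 1.96 * out["auprc_sd"] / np.sqrt(out["n"])
        out["auroc_ci95"] = 1.96 * out["auroc_sd"] / np.sqrt(out["n"])
        return out


def compare_models(values_a, values_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test on per-repetition metrics.

    Degenerate zero-variance inputs are handled deterministically:
    p = 1.0 when the means are equal, p = 0.0 otherwise (t = 0 or +/-inf).
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("need >= 2 values per side for Welch's test")
    if np.all(a == a[0]) and np.all(b == b[0]):
        if a[0] == b[0]:
            return 0.0, 1.0
        return (math.copysign(math.inf, a[0] - b[0]), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def diagnostics(z, labels, n_bins: int = 30) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent-space diagnostics for a labelled test fold.

    Returns (marginal summary, squared-norm histogram).  For a well-fitted
    flow, unaffected rows should look standard normal per coordinate and
    their squared norms chi-square with d degrees of freedom; affected rows
    should sit farther from the origin.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    labels = np.asarray(labels, dtype=float).ravel()
    d = z.shape[1]
    rows = []
    classes = {"unaffected": labels == 0, "affected": labels == 1}
    for cls, mask in classes.items():
        if mask.sum() == 0:
            rows.append({"class": cls, "coordinate": None, "n": 0,
                         "mean": np.nan, "sd": np.nan})
            continue
        for j in range(d):
            col = z[mask, j]
            rows.append({"class": cls, "coordinate": j, "n": int(mask.sum()),
                         "mean": float(col.mean()),
                         "sd": float(col.std(ddof=1)) if mask.sum() > 1
                         else np.nan})
    marginal = pd.DataFrame(rows)

    sq = (z * z).sum(axis=1)
    finite_max = sq.max() if len(sq) else 1.0
    edges = np.linspace(0.0, max(finite_max, 1e-9), n_bins + 1)
    hist_rows = []
    for cls, mask in classes.items():
        counts, _ = np.histogram(sq[mask], bins=edges)
        for b in range(n_bins):
            hist_rows.append({"class": cls, "bin_left": edges[b],
                              "bin_right": edges[b + 1],
                              "count": int(counts[b])})
    histogram = pd.DataFrame(hist_rows)
    return marginal, histogram
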