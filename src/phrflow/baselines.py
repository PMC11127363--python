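"""Reference models the flow is compared against.

Two families share one scorer interface (``score(X, C) -> array``, higher =
more positive/anomalous):

* supervised classifiers (SVM, random forest, LightGBM, XGBoost) with
  inverse-frequency class weights and hyperparameters tuned by stratified
  five-fold cross-validation maximizing average precision;
* classical one-class detectors (one-class SVM, isolation forest, Gaussian
  mixture) fitted on unaffected rows only — handing them any affected row
  is a protocol violation, not a warning.

The condition argument ``C`` is accepted for interface uniformity with the
flow scorer; baseline models simply concatenate it onto the features, which
mirrors giving a plain classifier access to age and gender as columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import IsolationForest, RandomForestClassifier
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC, OneClassSVM

from .exceptions import ConfigurationError, ProtocolViolationError

__all__ = [
    "BaselineSpec",
    "GmmParams",
    "Scorer",
    "fit_supervised",
    "fit_semisupervised",
    "apply_resampler",
]

_SUPERVISED = ("svm", "random_forest", "lgbm", "xgboost")
_SEMISUPERVISED = ("one_class_svm", "isolation_forest", "gmm")


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline to fit, with an optional hyperparameter grid override."""

    model: str
    grid: dict | None = None
    class_weight: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _SUPERVISED + _SEMISUPERVISED:
            raise ConfigurationError(f"unknown baseline {self.model!r}")


@dataclass(frozen=True)
class GmmParams:
    """Mixture f(x) = sum_i w_i N(x; mu_i, Sigma_i)."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray  # (m, d, d), full

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ConfigurationError("mixture weights must form a simplex")

    def log_density(self, X) -> np.ndarray:
        """Closed-form mixture log-density (log-sum-exp over components)."""
        from scipy.stats import multivariate_normal

        X = np.atleast_2d(np.asarray(X, dtype=float))
        comps = np.stack(
            [
                np.log(self.weights[i])
                + multivariate_normal.logpdf(
                    X, mean=self.means[i], cov=self.covariances[i]
                )
                for i in range(len(self.weights))
            ]
        )
        from scipy.special import logsumexp

        return logsumexp(comps, axis=0)


class Scorer:
    """Fitted model with a uniform scoring surface."""

    def __init__(self, name: str, score_fn, chosen_params: dict | None = None,
                 estimator=None) -> None:
        self.name = name
        self._score_fn = score_fn
        self.chosen_params = chosen_params or {}
        self.estimator = estimator

    def score(self, X, C=None) -> np.ndarray:
        import warnings

        X = np.atleast_2d(np.asarray(X, dtype=float))
        if C is not None:
            C = np.atleast_2d(np.asarray(C, dtype=float))
            X = np.concatenate([X, C], axis=1)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*feature names.*")
            return np.asarray(self._score_fn(X), dtype=float).ravel()


class ConstantScorer(Scorer):
    """Uninformative reference: same score for every row (AUPRC = base rate)."""

    def __init__(self, value: float = 0.0) -> None:
        super().__init__("constant", lambda X: np.full(len(X), value))


def _default_grids(seed: int, class_weight: bool) -> dict[str, tuple]:
    import lightgbm as lgb
    import xgboost as xgb

    cw = "balanced" if class_weight else None
    return {
        "svm": (
            SVC(kernel="rbf", class_weight=cw, random_state=seed),
            {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
        ),
        "random_forest": (
            RandomForestClassifier(
                n_estimators=300, class_weight=cw, random_state=seed, n_jobs=1
            ),
            {"max_depth": [None, 8]},
        ),
        "lgbm": (
            lgb.LGBMClassifier(
                n_estimators=200, class_weight=cw, random_state=seed,
                verbose=-1, n_jobs=1,
            ),
            {"num_leaves": [15, 31]},
        ),
        "xgboost": (
            xgb.XGBClassifier(
                n_estimators=200, random_state=seed, n_jobs=1,
                eval_metric="logloss",
            ),
            {"max_depth": [3, 6]},
        ),
    }


def _risk_score_fn(est):
    if hasattr(est, "decision_function"):
        return est.decision_function
    return lambda X: est.predict_proba(X)[:, 1]


def fit_supervised(spec: BaselineSpec, X, y, C=None, cv_folds: int = 5) -> Scorer:
    """Fit a supervised classifier, tuning hyperparameters by stratified
    ``cv_folds``-fold cross-validation on average precision."""
    if spec.model not in _SUPERVISED:
        raise ConfigurationError(f"{spec.model!r} is not a supervised baseline")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if C is not None:
        X = np.concatenate([X, np.atleast_2d(np.asarray(C, dtype=float))], axis=1)
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ConfigurationError("supervised fit needs both classes in train")

    est, grid = _default_grids(spec.seed, spec.class_weight)[spec.model]
    if spec.model == "xgboost" and spec.class_weight:
        n_pos = (y == 1).sum()
        est.set_params(scale_pos_weight=(y == 0).sum() / max(n_pos, 1))
    if spec.grid is not None:
        grid = spec.grid

    n_pos = int((y == 1).sum())
    folds = min(cv_folds, n_pos, int((y == 0).sum()))
    if folds >= 2 and sum(len(v) for v in grid.values()) > len(grid):
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
        search = GridSearchCV(est, grid, scoring="average_precision", cv=cv,
                              n_jobs=1)
        search.fit(X, y)
        best = search.best_estimator_
        chosen = search.best_params_
    else:
        # too few minority rows to cross-validate, or a singleton grid
        best = est.set_params(**{k: v[0] for k, v in grid.items()})
        best.fit(X, y)
        chosen = {k: v[0] for k, v in grid.items()}
    return Scorer(spec.model, _risk_score_fn(best), chosen, estimator=best)


def fit_semisupervised(spec: BaselineSpec, X, C=None, labels=None) -> Scorer:
    """Fit a one-class detector on unaffected rows; output is oriented so
    higher = more anomalous (the GMM scores negative log-likelihood)."""
    if spec.model not in _SEMISUPERVISED:
        raise ConfigurationError(f"{spec.model!r} is not a one-class baseline")
    if labels is not None:
        n_pos = int(np.nansum(np.asarray(labels, dtype=float)))
        if n_pos != 0:
            raise ProtocolViolationError(
                f"{n_pos} affected row(s) passed to a semi-supervised fit"
            )
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if C is not None:
        X = np.concatenate([X, np.atleast_2d(np.asarray(C, dtype=float))], axis=1)

    if spec.model == "one_class_svm":
        grid = spec.grid or {"nu": 0.1, "gamma": "scale"}
        est = OneClassSVM(**grid).fit(X)
        return Scorer("one_class_svm", lambda Z: -est.decision_function(Z),
                      grid, estimator=est)
    if spec.model == "isolation_forest":
        grid = spec.grid or {"n_estimators": 200}
        est = IsolationForest(random_state=spec.seed, **grid).fit(X)
        return Scorer("isolation_forest", lambda Z: -est.score_samples(Z),
                      grid, estimator=est)
    # GMM: component count chosen by BIC on the unaffected rows themselves
    m_grid = (spec.grid or {}).get("n_components", [1, 2, 4, 8])
    fits = []
    for m in m_grid:
        if m > len(X):
            continue
        g = GaussianMixture(n_components=m, covariance_type="full",
                            random_state=spec.seed, reg_covar=1e-4).fit(X)
        fits.append((g.bic(X), m, g))
    bic, m, gmm = min(fits, key=lambda t: t[0])
    return Scorer("gmm", lambda Z: -gmm.score_samples(Z),
                  {"n_components": m, "bic": float(bic)}, estimator=gmm)


def gmm_params(scorer: Scorer) -> GmmParams:
    """Extract the fitted mixture parameters from a GMM scorer."""
    gm = scorer.estimator
    if not isinstance(gm, GaussianMixture):
        raise ConfigurationError("scorer does not wrap a Gaussian mixture")
    return GmmParams(gm.weights_.copy(), gm.means_.copy(),
                     gm.covariances_.copy())


# -- resampling -----------------------------------------------------------

def apply_resampler(name: str, X, y, seed: int, k_neighbors: int = 5
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Classical class-imbalance resamplers, deterministic per seed.

    ``smote``/``adasyn`` add synthetic minority rows on segments between
    minority neighbors until classes balance; ``tomek_link`` removes the
    majority member of each opposite-class mutual-nearest-neighbor pair.
    """
    from . import resampling

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ConfigurationError("resampling needs both classes present")
    if name == "smote":
        return resampling.smote(X, y, seed=seed, k_neighbors=k_neighbors)
    if name == "adasyn":
        return resampling.adasyn(X, y, seed=seed, k_neighbors=k_neighbors)
    if name == "tomek_link":
        return resampling.tomek_links(X, y)
    raise ConfigurationError(f"unknown resampler {name!r}")
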