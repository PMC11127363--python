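"""Preprocessing chain for tabular cohort data.

The chain is: log(1+x) transform of right-skewed features -> drop of
configured irrelevant features (including the target's own biomarker) ->
chained-regression imputation of missing values -> robust (median/IQR)
scaling -> PCA collapse of configured multicollinear feature groups.  Age
and gender are routed out of the feature matrix into a separate condition
matrix.

Everything is fitted on training rows only; `transform` is a pure function
of the fitted state, so applying it to test rows cannot leak information
back into the fit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .exceptions import ConfigurationError, SchemaError
from .synthetic import CohortTable

__all__ = [
    "PcaGroup",
    "PreprocessPlan",
    "Preprocessor",
    "split_train_test",
    "fit_preprocessor",
    "transform",
]


@dataclass(frozen=True)
class PcaGroup:
    name: str
    members: tuple[str, ...]
    n_components: int = 1


@dataclass(frozen=True)
class PreprocessPlan:
    """Declarative description of the preprocessing to apply.

    The judgment calls (which features are skewed, which are irrelevant,
    which form multicollinear groups) are configuration, not code.
    """

    log_features: tuple[str, ...] = ()
    drop_features: tuple[str, ...] = ()
    pca_groups: tuple[PcaGroup, ...] = ()
    target_label: str | None = None
    condition_columns: tuple[str, str] = ("age", "gender")

    def __post_init__(self) -> None:
        if set(self.log_features) & set(self.drop_features):
            raise ConfigurationError("log_features and drop_features overlap")
        seen: set[str] = set()
        for g in self.pca_groups:
            overlap = seen & set(g.members)
            if overlap:
                raise ConfigurationError(
                    f"pca groups share members: {sorted(overlap)}"
                )
            if g.n_components < 1 or g.n_components > len(g.members):
                raise ConfigurationError(
                    f"pca group {g.name!r}: bad n_components"
                )
            seen |= set(g.members)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessPlan":
        groups = tuple(
            PcaGroup(g["name"], tuple(g["members"]), int(g.get("n_components", 1)))
            for g in d.get("pca_groups", [])
        )
        return cls(
            log_features=tuple(d.get("log_features", ())),
            drop_features=tuple(d.get("drop_features", ())),
            pca_groups=groups,
            target_label=d.get("target_label"),
            condition_columns=tuple(d.get("condition_columns", ("age", "gender"))),
        )

    def to_dict(self) -> dict:
        return {
            "log_features": list(self.log_features),
            "drop_features": list(self.drop_features),
            "pca_groups": [
                {"name": g.name, "members": list(g.members),
                 "n_components": g.n_components}
                for g in self.pca_groups
            ],
            "target_label": self.target_label,
            "condition_columns": list(self.condition_columns),
        }


def split_train_test(
    cohort: CohortTable | pd.DataFrame,
    ratio: float,
    seed: int,
    target_label: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split of row positions, |train| = round(ratio * n).

    Rows with a missing value in the target label are excluded entirely
    before splitting.  Returns positional indices into the cohort table.
    """
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError("split ratio must be in (0, 1)")
    if isinstance(cohort, CohortTable):
        n_total = cohort.n
        target = (
            cohort.labels[target_label] if target_label is not None else None
        )
    else:
        n_total = len(cohort)
        target = cohort[target_label] if target_label is not None else None
    if n_total == 0:
        raise ConfigurationError("cannot split an empty cohort")
    eligible = np.arange(n_total)
    if target is not None:
        eligible = eligible[target.notna().to_numpy()]
    if len(eligible) == 0:
        raise ConfigurationError("no rows with an observed target label")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(eligible)
    n_train = int(round(ratio * len(eligible)))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _iqr_scale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column medians and IQRs; zero IQR -> scale 1 (center-only)."""
    center = np.nanmedian(x, axis=0)
    q75 = np.nanpercentile(x, 75, axis=0)
    q25 = np.nanpercentile(x, 25, axis=0)
    scale = q75 - q25
    scale[scale == 0.0] = 1.0
    return center, scale


class Preprocessor:
    """Fitted preprocessing state: imputer, robust scaler, per-group PCA.

    Construct via :func:`fit_preprocessor` (or ``Preprocessor().fit(...)``).
    """

    def __init__(self) -> None:
        self.plan: PreprocessPlan | None = None
        self.input_columns_: list[str] | None = None
        self.feature_columns_: list[str] | None = None
        self.imputer_: IterativeImputer | None = None
        self.center_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.cond_center_: np.ndarray | None = None
        self.cond_scale_: np.ndarray | None = None
        self.pca_: dict[str, PCA] = {}
        self.pca_components_: dict[str, int] = {}
        self.output_columns_: list[str] | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, train: pd.DataFrame, plan: PreprocessPlan, seed: int = 0
            ) -> "Preprocessor":
        if len(train) == 0:
            raise ConfigurationError("cannot fit preprocessor on empty data")
        self.plan = plan
        cond = list(plan.condition_columns)
        for c in cond:
            if c not in train.columns:
                raise SchemaError(f"condition column {c!r} not in data")
        self.input_columns_ = [c for c in train.columns]
        feats = [
            c for c in train.columns
            if c not in cond and c not in plan.drop_features
        ]
        if not feats:
            raise ConfigurationError("no feature columns left after dropping")
        self.feature_columns_ = feats

        X = self._log_block(train[feats])

        self.imputer_ = IterativeImputer(
            max_iter=10, tol=1e-3, random_state=seed, sample_posterior=False,
            keep_empty_features=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xi = self.imputer_.fit_transform(X.to_numpy(dtype=float))

        self.center_, self.scale_ = _iqr_scale(Xi)
        Xs = (Xi - self.center_) / self.scale_
        Xs_df = pd.DataFrame(Xs, columns=feats, index=train.index)

        # condition scaling: age centred/scaled, binary gender passed through
        age_col, gender_col = cond
        age = train[age_col].to_numpy(dtype=float)
        a_center, a_scale = _iqr_scale(age[:, None])
        self.cond_center_ = np.array([a_center[0], 0.0])
        self.cond_scale_ = np.array([a_scale[0], 1.0])

        self.pca_ = {}
        self.pca_components_ = {}
        passthrough = list(feats)
        for g in plan.pca_groups:
            missing = [m for m in g.members if m not in feats]
            if missing:
                raise ConfigurationError(
                    f"pca group {g.name!r} members not available: {missing}"
                )
            k = g.n_components
            max_k = min(len(g.members), len(train))
            if k > max_k:
                warnings.warn(
                    f"pca group {g.name!r}: reducing components {k} -> {max_k}"
                )
                k = max_k
            pca = PCA(n_components=k, svd_solver="full", random_state=seed)
            pca.fit(Xs_df[list(g.members)].to_numpy())
            self.pca_[g.name] = pca
            self.pca_components_[g.name] = k
            for m in g.members:
                passthrough.remove(m)

        self.output_columns_ = passthrough + [
            f"{g.name}_pc{i + 1}"
            for g in plan.pca_groups
            for i in range(self.pca_components_[g.name])
        ]
        return self

    # -- transforming ------------------------------------------------------

    def transform(self, rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Pure function of the fitted state: (feature matrix, condition matrix)."""
        if self.plan is None:
            raise ConfigurationError("preprocessor is not fitted")
        if set(self.input_columns_) - set(rows.columns):
            raise SchemaError(
                "input is missing columns "
                f"{sorted(set(self.input_columns_) - set(rows.columns))}"
            )
        plan = self.plan
        feats = self.feature_columns_
        X = self._log_block(rows[feats])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xi = self.imputer_.transform(X.to_numpy(dtype=float))
        Xs = (Xi - self.center_) / self.scale_
        Xs_df = pd.DataFrame(Xs, columns=feats, index=rows.index)

        grouped = [m for g in plan.pca_groups for m in g.members]
        out = Xs_df.drop(columns=grouped)
        for g in plan.pca_groups:
            comp = self.pca_[g.name].transform(Xs_df[list(g.members)].to_numpy())
            for i in range(self.pca_components_[g.name]):
                out[f"{g.name}_pc{i + 1}"] = comp[:, i]
        out = out[self.output_columns_]

        age_col, gender_col = plan.condition_columns
        cond = pd.DataFrame(
            {
                age_col: (rows[age_col].to_numpy(dtype=float)
                          - self.cond_center_[0]) / self.cond_scale_[0],
                gender_col: rows[gender_col].to_numpy(dtype=float),
            },
            index=rows.index,
        )
        return out, cond

    def _log_block(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X.copy()
        for name in self.plan.log_features:
            if name in X.columns:
                if (X[name].dropna() < 0).any():
                    raise ConfigurationError(
                        f"log feature {name!r} has negative values"
                    )
                X[name] = np.log1p(X[name])
        return X

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_output_features(self) -> int:
        return len(self.output_columns_)

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {
            "center": self.center_,
            "scale": self.scale_,
            "cond_center": self.cond_center_,
            "cond_scale": self.cond_scale_,
        }
        for name, pca in self.pca_.items():
            arrays[f"pca_{name}_components"] = pca.components_
            arrays[f"pca_{name}_mean"] = pca.mean_
        for i, est in enumerate(getattr(self.imputer_, "imputation_sequence_", [])):
            arrays[f"imputer_{i}_coef"] = np.asarray(est.estimator.coef_)
            arrays[f"imputer_{i}_intercept"] = np.atleast_1d(
                est.estimator.intercept_
            )
        return arrays

    def state_digest(self) -> str:
        """SHA-256 over every fitted array plus the metadata; used by the
        leakage-guard tests to assert test rows never influence the fit."""
        h = hashlib.sha256()
        meta = json.dumps(
            {
                "plan": self.plan.to_dict(),
                "input_columns": self.input_columns_,
                "output_columns": self.output_columns_,
            },
            sort_keys=True,
        )
        h.update(meta.encode())
        for key in sorted(self.state_arrays()):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.state_arrays()[key]).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        import pickle

        meta = {
            "plan": self.plan.to_dict(),
            "input_columns": self.input_columns_,
            "feature_columns": self.feature_columns_,
            "output_columns": self.output_columns_,
        }
        with open(path, "wb") as fh:
            pickle.dump({"meta": meta, "state": self.__dict__}, fh)

    @classmethod
    def load(cls, path) -> "Preprocessor":
        import pickle

        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        obj = cls()
        obj.__dict__.update(payload["state"])
        return obj


def fit_preprocessor(
    train: pd.DataFrame, plan: PreprocessPlan, seed: int = 0
) -> Preprocessor:
    """Fit the preprocessing chain on training rows only."""
    return Preprocessor().fit(train, plan, seed=seed)


def plan_for_target(feats, rules, target_label: str) -> PreprocessPlan:
    """Default plan for a generated cohort: log-transform the right-skewed
    features, drop the target's own biomarker, collapse the smoking block
    to one component."""
    rule = next((r for r in rules if r.label_name == target_label), None)
    if rule is None:
        raise ConfigurationError(f"no disease rule named {target_label!r}")
    log_feats = tuple(
        f.name for f in feats
        if f.family == "lognormal" and f.name != rule.biomarker
    )
    groups = []
    smoking = tuple(f.name for f in feats if f.block_id == "smoking")
    if smoking and rule.biomarker not in smoking:
        groups.append(PcaGroup("smoking", smoking, 1))
    return PreprocessPlan(
        log_features=log_feats,
        drop_features=(rule.biomarker,),
        pca_groups=tuple(groups),
        target_label=target_label,
    )


def transform(
    state: Preprocessor, rows: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply a fitted preprocessor; returns (features, conditions)."""
    return state.transform(rows)
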