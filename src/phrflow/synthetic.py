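"""Synthetic personal-health-record (PHR) cohorts.

Real PHR studies of chronic disease work with small, demographically
structured cohorts: a few hundred participants, a mix of roughly normal and
right-skewed biomarkers (transaminases, triglycerides, daily step counts),
blocks of strongly correlated survey variables, missing entries, and disease
labels defined by thresholding a biomarker.  This module generates cohorts
with exactly that structure so the full modelling pipeline — preprocessing,
density modelling, anomaly scoring, imbalance experiments — can be exercised
and tested end to end without access to any private dataset.

Demographics are specified exactly (per age-bin male/female counts, not
sampled), features are drawn from per-feature families with optional
age/gender effects and equicorrelated blocks, and labels are deterministic
threshold functions of the complete (pre-missingness) feature values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "AgeBin",
    "DemographicsSpec",
    "FeatureSpec",
    "DiseaseRule",
    "CohortTable",
    "generate_cohort",
    "calibrate_base_rate",
    "summarize_prevalence",
    "default_cohort_spec",
]

_FAMILIES = ("gaussian", "lognormal", "categorical-ordinal", "correlated-block-member")

# Age is centred/scaled before effect coefficients are applied so that
# age_coef has the interpretation "shift per ~decade of age".
_AGE_CENTER = 40.0
_AGE_SCALE = 10.0


@dataclass(frozen=True)
class AgeBin:
    label: str
    min_age: float
    max_age: float
    male_count: int
    female_count: int


@dataclass(frozen=True)
class DemographicsSpec:
    """Exact per-age-bin, per-gender participant counts."""

    bins: tuple[AgeBin, ...]

    def __post_init__(self) -> None:
        for b in self.bins:
            if b.male_count < 0 or b.female_count < 0:
                raise ConfigurationError(f"negative count in age bin {b.label!r}")
            if b.max_age < b.min_age:
                raise ConfigurationError(f"empty age range in bin {b.label!r}")
        ordered = sorted(self.bins, key=lambda b: b.min_age)
        for lo, hi in zip(ordered, ordered[1:]):
            if hi.min_age <= lo.max_age:
                raise ConfigurationError(
                    f"overlapping age bins {lo.label!r} and {hi.label!r}"
                )

    @property
    def total(self) -> int:
        return sum(b.male_count + b.female_count for b in self.bins)

    @property
    def total_male(self) -> int:
        return sum(b.male_count for b in self.bins)

    @property
    def total_female(self) -> int:
        return sum(b.female_count for b in self.bins)

    def scaled(self, factor: int) -> "DemographicsSpec":
        """Multiply every count by an integer factor (for large calibration runs)."""
        return DemographicsSpec(
            tuple(
                replace(b, male_count=b.male_count * factor,
                        female_count=b.female_count * factor)
                for b in self.bins
            )
        )

    @classmethod
    def reference_cohort(cls) -> "DemographicsSpec":
        """The default 706-participant demographic table (315 male, 391 female)."""
        return cls(
            (
                AgeBin("19", 19, 19, 0, 1),
                AgeBin("20-29", 20, 29, 45, 127),
                AgeBin("30-39", 30, 39, 98, 130),
                AgeBin("40-49", 40, 49, 104, 89),
                AgeBin("50-59", 50, 59, 68, 44),
            )
        )


@dataclass(frozen=True)
class FeatureSpec:
    """One feature column of the synthetic cohort.

    ``family`` selects the marginal shape; ``age_coef``/``gender_coef`` shift
    the (latent) mean per standardized decade of age and for male gender;
    ``block_id`` puts the feature into an equicorrelated block whose members
    share pairwise correlation ``block_rho``.  Lognormal features apply the
    shifts on the log scale and are strictly positive.
    """

    name: str
    family: str = "gaussian"
    mean: float = 0.0
    sigma: float = 1.0
    age_coef: float = 0.0
    gender_coef: float = 0.0
    missing_rate: float = 0.0
    block_id: str | None = None
    block_rho: float | None = None
    n_levels: int | None = None  # categorical-ordinal only

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown feature family {self.family!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError(f"{self.name}: missing_rate must be in [0, 1]")
        if self.sigma <= 0:
            raise ConfigurationError(f"{self.name}: sigma must be positive")
        if self.family == "correlated-block-member" and self.block_id is None:
            raise ConfigurationError(
                f"{self.name}: block members need block_id and block_rho"
            )
        if self.block_id is not None:
            if self.block_rho is None or not 0.0 < self.block_rho < 1.0:
                raise ConfigurationError(f"{self.name}: block_rho must be in (0, 1)")
        if self.family == "categorical-ordinal" and (self.n_levels or 0) < 2:
            raise ConfigurationError(f"{self.name}: categorical needs n_levels >= 2")


@dataclass(frozen=True)
class DiseaseRule:
    """Binary disease label from thresholding one biomarker."""

    label_name: str
    biomarker: str
    direction: str  # "above" | "below"
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ConfigurationError(
                f"{self.label_name}: direction must be 'above' or 'below'"
            )

    def apply(self, features: pd.DataFrame) -> pd.Series:
        """Label each row; rows with a missing biomarker get a missing label."""
        if self.biomarker not in features.columns:
            raise ConfigurationError(
                f"rule {self.label_name!r} references unknown feature "
                f"{self.biomarker!r}"
            )
        x = features[self.biomarker]
        if self.direction == "above":
            lab = (x > self.threshold).astype(float)
        else:
            lab = (x < self.threshold).astype(float)
        lab[x.isna()] = np.nan
        lab.name = self.label_name
        return lab


@dataclass
class CohortTable:
    """Participant-by-feature table with condition columns and labels.

    ``features`` may contain missing entries; ``complete_features`` holds the
    latent complete values the labels were derived from (kept so label
    determinism is checkable and so calibration can use full marginals).
    """

    features: pd.DataFrame
    complete_features: pd.DataFrame
    age: pd.Series
    gender: pd.Series  # 0 = female, 1 = male
    labels: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        """Single flat table: age, gender, features, labels."""
        return pd.concat(
            [self.age.rename("age"), self.gender.rename("gender"),
             self.features, self.labels],
            axis=1,
        )

    def sidecar_config(
        self,
        feats: Sequence[FeatureSpec] | None = None,
    ) -> dict:
        """Metadata describing column roles, for CSV round-tripping."""
        cfg: dict = {
            "condition_columns": ["age", "gender"],
            "label_columns": list(self.labels.columns),
            "feature_columns": list(self.features.columns),
        }
        if feats is not None:
            cfg["skewed_features"] = [f.name for f in feats if f.family == "lognormal"]
            blocks: dict[str, list[str]] = {}
            for f in feats:
                if f.block_id is not None:
                    blocks.setdefault(f.block_id, []).append(f.name)
            cfg["blocks"] = blocks
        return cfg


def _draw_demographics(
    demo: DemographicsSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    ages, genders = [], []
    for b in demo.bins:
        k = b.male_count + b.female_count
        # ages uniform within the bin; the table only fixes bin membership
        ages.append(rng.uniform(b.min_age, b.max_age + 1.0, size=k))
        genders.append(np.concatenate([np.ones(b.male_count), np.zeros(b.female_count)]))
    if not ages:
        return np.empty(0), np.empty(0)
    age = np.concatenate(ages)
    gender = np.concatenate(genders)
    perm = rng.permutation(len(age))
    return age[perm], gender[perm]


def _draw_features(
    feats: Sequence[FeatureSpec],
    age: np.ndarray,
    gender: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(age)
    age_std = (age - _AGE_CENTER) / _AGE_SCALE

    # one shared factor per block, validated for a consistent rho
    block_rho: dict[str, float] = {}
    for f in feats:
        if f.block_id is not None:
            prev = block_rho.setdefault(f.block_id, float(f.block_rho))
            if prev != float(f.block_rho):
                raise ConfigurationError(
                    f"block {f.block_id!r} members disagree on block_rho"
                )
    block_factor = {bid: rng.standard_normal(n) for bid in sorted(block_rho)}

    cols: dict[str, np.ndarray] = {}
    for f in feats:
        if f.block_id is not None:
            rho = block_rho[f.block_id]
            eps = np.sqrt(rho) * block_factor[f.block_id] + np.sqrt(
                1.0 - rho
            ) * rng.standard_normal(n)
        else:
            eps = rng.standard_normal(n)
        latent = f.mean + f.age_coef * age_std + f.gender_coef * gender + f.sigma * eps
        if f.family == "lognormal":
            cols[f.name] = np.exp(latent)
        elif f.family == "categorical-ordinal":
            L = int(f.n_levels)
            # discretize the latent by its own distribution's quantiles
            edges = np.quantile(latent, np.linspace(0, 1, L + 1)[1:-1])
            cols[f.name] = np.searchsorted(edges, latent).astype(float)
        else:
            cols[f.name] = latent
    return pd.DataFrame(cols, index=pd.RangeIndex(n))


def generate_cohort(
    demo: DemographicsSpec,
    feats: Sequence[FeatureSpec],
    rules: Sequence[DiseaseRule],
    seed: int,
) -> CohortTable:
    """Generate a cohort: exact demographics, family-structured features,
    threshold labels, then missingness.

    Labels are computed on the complete latent values *before* missingness is
    injected; afterwards a label is masked to missing wherever its biomarker
    was masked, matching how a threshold label could actually be assigned.
    Deterministic for a fixed seed.
    """
    names = [f.name for f in feats]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate feature names")
    for r in rules:
        if r.biomarker not in names:
            raise ConfigurationError(
                f"rule {r.label_name!r} references unknown feature {r.biomarker!r}"
            )

    rng = np.random.default_rng(seed)
    age_arr, gender_arr = _draw_demographics(demo, rng)
    n = len(age_arr)
    age = pd.Series(age_arr, name="age")
    gender = pd.Series(gender_arr, name="gender")

    complete = _draw_features(feats, age_arr, gender_arr, rng)
    labels = pd.DataFrame(
        {r.label_name: r.apply(complete) for r in rules}, index=complete.index
    )
    if not rules:
        labels = pd.DataFrame(index=complete.index)

    observed = complete.copy()
    for f in feats:
        if f.missing_rate > 0 and n > 0:
            mask = rng.random(n) < f.missing_rate
            observed.loc[mask, f.name] = np.nan
    # a threshold label cannot be assigned when its biomarker is unobserved
    for r in rules:
        labels.loc[observed[r.biomarker].isna(), r.label_name] = np.nan

    return CohortTable(
        features=observed,
        complete_features=complete,
        age=age,
        gender=gender,
        labels=labels,
    )


def calibrate_base_rate(
    rule: DiseaseRule,
    target_rate: float,
    feats: Sequence[FeatureSpec],
    demo: DemographicsSpec,
    seed: int,
    calibration_n: int = 50_000,
) -> DiseaseRule:
    """Set the rule threshold to the biomarker quantile that realizes
    ``target_rate`` prevalence on a large simulated cohort."""
    if not 0.0 < target_rate < 1.0:
        raise ConfigurationError("target_rate must lie strictly in (0, 1)")
    if demo.total == 0:
        raise ConfigurationError("cannot calibrate on an empty demographics spec")
    factor = max(1, int(np.ceil(calibration_n / demo.total)))
    big = generate_cohort(demo.scaled(factor), feats, rules=(), seed=seed)
    values = big.complete_features[rule.biomarker].to_numpy()
    q = 1.0 - target_rate if rule.direction == "above" else target_rate
    return replace(rule, threshold=float(np.quantile(values, q)))


def summarize_prevalence(cohort: CohortTable) -> pd.DataFrame:
    """Per-label positive count and percent among rows with an observed label.

    percent = 100 * count / n_observed rounded to one decimal; NaN when no
    label is observed at all.
    """
    rows = []
    for name in cohort.labels.columns:
        col = cohort.labels[name]
        observed = col.dropna()
        count = int((observed == 1).sum())
        if len(observed) == 0:
            pct = np.nan
        else:
            pct = round(100.0 * count / len(observed), 1)
        rows.append({"label": name, "count": count, "percent": pct,
                     "n_observed": len(observed)})
    return pd.DataFrame(rows).set_index("label")


def _default_features() -> tuple[FeatureSpec, ...]:
    # A compact emulation of a check-up + lifestyle + genetic feature panel:
    # right-skewed liver enzymes / triglycerides / step counts, correlated
    # lipid, blood-pressure and smoking blocks, an ordinal genetic-risk
    # grade, and mild but real age/gender structure throughout.
    return (
        FeatureSpec("bmi", "gaussian", mean=23.5, sigma=3.2,
                    age_coef=0.35, gender_coef=1.2, missing_rate=0.01,
                    block_id="metabolic", block_rho=0.55),
        FeatureSpec("fasting_glucose", "gaussian", mean=93.0, sigma=10.0,
                    age_coef=2.5, gender_coef=2.0, missing_rate=0.02,
                    block_id="metabolic", block_rho=0.55),
        FeatureSpec("ast", "lognormal", mean=3.05, sigma=0.30,
                    age_coef=0.03, gender_coef=0.15, missing_rate=0.02,
                    block_id="liver", block_rho=0.7),
        FeatureSpec("alt", "lognormal", mean=2.95, sigma=0.45,
                    age_coef=0.02, gender_coef=0.35, missing_rate=0.02,
                    block_id="liver", block_rho=0.7),
        FeatureSpec("neutral_fat", "lognormal", mean=4.55, sigma=0.45,
                    age_coef=0.08, gender_coef=0.30, missing_rate=0.02,
                    block_id="metabolic", block_rho=0.55),
        FeatureSpec("total_cholesterol", "correlated-block-member", mean=193.0,
                    sigma=33.0, age_coef=4.0, gender_coef=2.0,
                    missing_rate=0.02, block_id="lipid", block_rho=0.6),
        FeatureSpec("ldl", "correlated-block-member", mean=116.0, sigma=30.0,
                    age_coef=3.5, gender_coef=3.0, missing_rate=0.02,
                    block_id="lipid", block_rho=0.6),
        FeatureSpec("hdl", "gaussian", mean=57.0, sigma=13.0,
                    age_coef=-0.5, gender_coef=-8.0, missing_rate=0.02),
        FeatureSpec("systolic_bp", "correlated-block-member", mean=118.0,
                    sigma=13.0, age_coef=2.5, gender_coef=6.0,
                    missing_rate=0.01, block_id="bp", block_rho=0.75),
        FeatureSpec("diastolic_bp", "correlated-block-member", mean=74.0,
                    sigma=9.5, age_coef=1.8, gender_coef=4.0,
                    missing_rate=0.01, block_id="bp", block_rho=0.75),
        FeatureSpec("steps_per_day", "lognormal", mean=8.9, sigma=0.5,
                    age_coef=-0.05, gender_coef=0.08, missing_rate=0.05),
        FeatureSpec("resting_heart_rate", "gaussian", mean=71.0, sigma=9.0,
                    age_coef=0.3, gender_coef=-2.0, missing_rate=0.05),
        FeatureSpec("smoking_years", "correlated-block-member", mean=0.0,
                    sigma=1.0, age_coef=0.5, gender_coef=1.1,
                    missing_rate=0.03, block_id="smoking", block_rho=0.8),
        FeatureSpec("cigarettes_per_day", "correlated-block-member", mean=0.0,
                    sigma=1.0, age_coef=0.2, gender_coef=1.2,
                    missing_rate=0.03, block_id="smoking", block_rho=0.8),
        FeatureSpec("secondhand_smoke", "correlated-block-member", mean=0.0,
                    sigma=1.0, age_coef=0.0, gender_coef=0.5,
                    missing_rate=0.03, block_id="smoking", block_rho=0.8),
        FeatureSpec("prs_glucose_grade", "categorical-ordinal", mean=0.0,
                    sigma=1.0, n_levels=5, missing_rate=0.0),
    )


# Default chronic-disease panel and target prevalences: a spectrum from
# common (~1/3) down to extreme imbalance (0.02), so the imbalance behaviour
# the package studies is representable out of the box.
_DEFAULT_RATES = {
    "obesity": ("bmi", "above", 0.33),
    "diabetes": ("fasting_glucose", "above", 0.02),
    "hypertriglyceridemia": ("neutral_fat", "above", 0.08),
    "dyslipidemia": ("ldl", "above", 0.08),
    "liver_dysfunction": ("alt", "above", 0.11),
    "hypertension": ("systolic_bp", "above", 0.34),
}


@lru_cache(maxsize=4)
def default_cohort_spec(
    seed: int = 0,
) -> tuple[DemographicsSpec, tuple[FeatureSpec, ...], tuple[DiseaseRule, ...]]:
    """Reference cohort spec: 706-person demographics, 16-feature panel,
    six threshold diseases calibrated to the default prevalence spectrum."""
    demo = DemographicsSpec.reference_cohort()
    feats = _default_features()
    rules = []
    for label, (biomarker, direction, rate) in _DEFAULT_RATES.items():
        raw = DiseaseRule(label, biomarker, direction, threshold=0.0)
        rules.append(
            calibrate_base_rate(raw, rate, feats, demo, seed=seed,
                                calibration_n=40_000)
        )
    return demo, feats, tuple(rules)
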