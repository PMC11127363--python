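"""Evaluation protocol: split plans, fold metrics, repetitions, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phrflow.baselines import ConstantScorer
from phrflow.evaluation import (
    compare_models,
    diagnostics,
    evaluate_model,
    make_split_plan,
    run_repetitions,
    undersample_positives,
)
from phrflow.exceptions import ConfigurationError, PhrflowError
from phrflow.metrics import auroc


def labels_vector(n_neg, n_pos, seed=0):
    y = np.concatenate([np.zeros(n_neg), np.ones(n_pos)])
    return np.random.default_rng(seed).permutation(y)


class _OracleScorer:
    """Scores equal to the true label (plus optional sign flip)."""

    def __init__(self, y, sign=1.0):
        self.y = np.asarray(y, dtype=float)
        self.sign = sign
        self._lookup = None

    def bind(self, X):
        self._X = X

    def score(self, X, C=None):
        # identify rows by exact match against the bound full matrix
        idx = [int(np.flatnonzero((self._X == row).all(axis=1))[0])
               for row in np.atleast_2d(X)]
        return self.sign * self.y[idx]


class TestSplitPlan:
    def test_extreme_imbalance_reference_counts(self):
        y = labels_vector(693, 13)
        plan = make_split_plan(y, seed=0)
        assert len(plan.train_idx) == 554
        assert len(plan.test_pool_idx) == 139
        sizes = sorted(len(s) for s in plan.affected_subsets)
        assert sizes == [2, 2, 3, 3, 3]
        for k in range(5):
            assert 0.0140 <= plan.fold_base_rate(k) <= 0.0215

    def test_minimal_case(self):
        y = labels_vector(10, 5)
        plan = make_split_plan(y, seed=1)
        assert len(plan.train_idx) == 8
        assert len(plan.test_pool_idx) == 2
        assert all(len(s) == 1 for s in plan.affected_subsets)

    def test_too_few_affected_rejected(self):
        with pytest.raises(ConfigurationError, match="folds"):
            make_split_plan(labels_vector(50, 4), seed=0)

    def test_conservation_and_disjointness(self):
        y = labels_vector(300, 23, seed=3)
        plan = make_split_plan(y, seed=4)
        affected = np.flatnonzero(y == 1)
        merged = np.sort(np.concatenate(plan.affected_subsets))
        assert np.array_equal(merged, affected)
        for k in range(plan.n_folds):
            fold = plan.fold_indices(k)
            assert len(np.intersect1d(plan.train_idx, fold)) == 0

    def test_missing_labels_excluded(self):
        y = np.concatenate([np.zeros(100), np.ones(10)])
        y[:7] = np.nan  # unlabeled rows, all among the negatives
        plan = make_split_plan(y, seed=0)
        used = np.concatenate([plan.train_idx, plan.test_pool_idx,
                               *plan.affected_subsets])
        assert not set(range(7)) & set(used.tolist())

    def test_deterministic_per_seed(self):
        y = labels_vector(200, 12)
        p1 = make_split_plan(y, seed=9)
        p2 = make_split_plan(y, seed=9)
        assert np.array_equal(p1.train_idx, p2.train_idx)

    def test_validation_subset_reservation(self):
        y = labels_vector(200, 12)
        plan = make_split_plan(y, seed=0, reserve_validation_subset=True)
        assert plan.validation_subset is not None
        merged = np.concatenate(plan.affected_subsets + [plan.validation_subset])
        assert np.array_equal(np.sort(merged), np.flatnonzero(y == 1))


class TestEvaluateModel:
    def _setup(self, n_neg=200, n_pos=10, d=4, seed=0):
        r = np.random.default_rng(seed)
        y = labels_vector(n_neg, n_pos, seed)
        X = r.normal(size=(len(y), d))
        plan = make_split_plan(y, seed=seed)
        return X, y, plan

    def test_oracle_scorer_is_perfect(self):
        X, y, plan = self._setup()
        scorer = _OracleScorer(y)
        scorer.bind(X)
        out = evaluate_model(scorer, plan, X, None, y)
        assert out["auroc"] == 1.0
        assert out["auprc"] == 1.0

    def test_anti_oracle_inverts(self):
        X, y, plan = self._setup()
        scorer = _OracleScorer(y, sign=-1.0)
        scorer.bind(X)
        out = evaluate_model(scorer, plan, X, None, y)
        assert out["auroc"] == 0.0

    def test_constant_scorer_auprc_equals_fold_base_rate(self):
        X, y, plan = self._setup()
        out = evaluate_model(ConstantScorer(), plan, X, None, y)
        expected = np.mean([plan.fold_base_rate(k) for k in range(5)])
        assert out["auprc"] == pytest.approx(expected)

    def test_nonfinite_scores_rejected(self):
        X, y, plan = self._setup()

        class BadScorer:
            def score(self, X, C=None):
                return np.full(len(X), np.nan)

        with pytest.raises(PhrflowError):
            evaluate_model(BadScorer(), plan, X, None, y)


class TestUndersampling:
    def test_reference_obesity_example(self):
        y = labels_vector(476, 230)
        keep = undersample_positives(y, 0.95, seed=0)
        n_pos = int(y[keep].sum())
        assert n_pos in (11, 12)  # round(0.95 * 230) = 218 or 219 removed
        assert y[keep].mean() == pytest.approx(0.024, abs=0.004)
        assert int((y[keep] == 0).sum()) == 476  # negatives untouched

    def test_zero_fraction_is_identity(self):
        y = labels_vector(50, 8)
        keep = undersample_positives(y, 0.0, seed=0)
        assert len(keep) == 58

    def test_half_of_four(self):
        y = labels_vector(20, 4)
        keep = undersample_positives(y, 0.5, seed=1)
        assert int(y[keep].sum()) == 2

    def test_fraction_one_rejected(self):
        with pytest.raises(ConfigurationError):
            undersample_positives(labels_vector(10, 2), 1.0, seed=0)


class TestRepetitions:
    def test_constant_metric_zero_ci(self):
        summary = run_repetitions(lambda s: {"m": 0.5}, n=10, seed_base=0)
        assert summary.means["m"] == 0.5
        assert summary.ci_half_widths["m"] == 0.0

    def test_same_seed_base_identical(self):
        def exp(seed):
            r = np.random.default_rng(seed)
            return {"m": float(r.random())}

        s1 = run_repetitions(exp, n=5, seed_base=3)
        s2 = run_repetitions(exp, n=5, seed_base=3)
        pd.testing.assert_frame_equal(s1.values, s2.values)

    def test_random_scorer_ci_covers_half(self):
        # coverage simulation: the CI for an uninformative scorer's AUROC
        # should contain 0.5 in the vast majority of meta-trials
        covered = 0
        for meta in range(100):
            def exp(seed, meta=meta):
                r = np.random.default_rng(seed)
                scores = r.random(400)
                y = np.zeros(400)
                y[r.choice(400, 40, replace=False)] = 1
                return {"auroc": auroc(scores, y)}

            s = run_repetitions(exp, n=20, seed_base=1000 * meta)
            lo = s.means["auroc"] - s.ci_half_widths["auroc"]
            hi = s.means["auroc"] + s.ci_half_widths["auroc"]
            covered += int(lo <= 0.5 <= hi)
        assert covered >= 90


class TestCompareModels:
    def test_identical_samples(self):
        t, p = compare_models([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_distinct_means(self):
        t, p = compare_models([0.2, 0.2, 0.2], [0.3, 0.3, 0.3])
        assert p == 0.0 and t < 0

    def test_matches_scipy_welch(self):
        r = np.random.default_rng(0)
        a, b = r.normal(0, 1, 30), r.normal(0.5, 2, 40)
        t, p = compare_models(a, b)
        t2, p2 = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(float(t2)) and p == pytest.approx(float(p2))

    def test_null_pvalues_uniform(self):
        r = np.random.default_rng(1)
        pvals = [compare_models(r.normal(size=50), r.normal(size=50))[1]
                 for _ in range(1000)]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_too_small_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_models([0.1], [0.2, 0.3])


class TestDiagnostics:
    def test_chi_square_mean_for_standard_normal(self, rng):
        z = rng.standard_normal((4000, 48))
        y = np.zeros(4000)
        marginal, hist = diagnostics(z, y)
        sq_mean = (z ** 2).sum(axis=1).mean()
        assert sq_mean == pytest.approx(48, rel=0.05)
        un = marginal[marginal["class"] == "unaffected"]
        assert np.allclose(un["mean"], 0.0, atol=0.1)
        assert np.allclose(un["sd"], 1.0, atol=0.1)

    def test_shifted_affected_has_larger_norms(self, rng):
        z0 = rng.standard_normal((500, 6))
        z1 = rng.standard_normal((50, 6)) + 1.5
        z = np.vstack([z0, z1])
        y = np.concatenate([np.zeros(500), np.ones(50)])
        _, hist = diagnostics(z, y)
        sq = (z ** 2).sum(axis=1)
        u = stats.mannwhitneyu(sq[y == 1], sq[y == 0], alternative="greater")
        assert u.pvalue < 1e-6

    def test_empty_class_marked_absent(self, rng):
        z = rng.standard_normal((30, 3))
        marginal, _ = diagnostics(z, np.zeros(30))
        aff = marginal[marginal["class"] == "affected"]
        assert len(aff) == 1 and aff.iloc[0]["n"] == 0
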