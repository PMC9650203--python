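"""Cohort statistics: rank correlations, group tests, the coarse
classification tree, cross-validation and confusion arithmetic."""

import numpy as np
import pytest

from modwalk import cohort, synth
from modwalk.cohort import (
    MULTI,
    TWO,
    confusion_report,
    cross_validate,
    fit_coarse_tree,
    fma_threshold_classifier,
    mann_whitney,
    predict_tree,
    printed_rule_tree,
    spearman,
)
from modwalk.errors import UndefinedCorrelationError
from modwalk.experiments import (
    anova_f_bruteforce,
    mwu_bruteforce,
    separable_split_oracle,
    spearman_bruteforce,
)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x**3).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_ties_match_bruteforce(self, rng):
        x = rng.integers(0, 5, 10).astype(float)
        y = rng.integers(0, 5, 10).astype(float)
        res = spearman(x, y)
        assert res.rho == pytest.approx(spearman_bruteforce(x, y), abs=1e-12)
        assert res.df == res.n_used - 2

    def test_pairwise_complete(self):
        x = np.array([1, 2, 3, 4, 5, np.nan])
        y = np.array([2, 4, 6, 8, np.nan, 12])
        res = spearman(x, y)
        assert res.n_used == 4
        assert res.rho == pytest.approx(1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman(np.ones(6), np.arange(6.0))


class TestMannWhitney:
    def test_full_separation(self):
        a = np.array([5.0, 6.0, 7.0])
        b = np.array([1.0, 2.0])
        u, _ = mann_whitney(a, b)
        assert u == 6.0  # n_a * n_b

    def test_identical_multisets(self):
        a = np.array([1.0, 2.0, 3.0])
        u, _ = mann_whitney(a, a)
        assert u == pytest.approx(4.5)  # n^2 / 2

    def test_small_samples_match_pair_count(self, rng):
        a = rng.integers(0, 8, 5).astype(float)
        b = rng.integers(0, 8, 6).astype(float)
        u, _ = mann_whitney(a, b)
        assert u == pytest.approx(mwu_bruteforce(a, b), abs=1e-12)


class TestAnova:
    def test_equal_means_f_near_zero(self, rng):
        g = {k: 5.0 + rng.standard_normal(20) for k in "abc"}
        f, p, _ = cohort.anova_posthoc(g)
        assert p > 0.05

    def test_bonferroni_capped(self, rng):
        g = {
            "a": rng.standard_normal(8),
            "b": rng.standard_normal(8),
            "c": rng.standard_normal(8) + 5.0,
        }
        _, _, pairwise = cohort.anova_posthoc(g)
        assert all(0.0 <= p <= 1.0 for p in pairwise.values())
        assert pairwise[("a", "b")] == 1.0  # raw p * 3 caps

    def test_f_matches_bruteforce(self, rng):
        samples = [rng.random(6), rng.random(5), rng.random(7)]
        f, _, _ = cohort.anova_posthoc({f"g{i}": s for i, s in enumerate(samples)})
        assert f == pytest.approx(anova_f_bruteforce(samples), abs=1e-9)


class TestCoarseTree:
    def test_separable_split_is_midpoint(self, rng):
        x = np.sort(rng.normal(size=12))
        y = np.array([TWO] * 5 + [MULTI] * 7)
        model = fit_coarse_tree(x[:, None], y, feature_names=("x",))
        assert model.root.threshold == pytest.approx(separable_split_oracle(x, y))
        assert model.n_splits == 1

    def test_single_class_single_leaf(self):
        X = np.random.default_rng(0).random((6, 2))
        model = fit_coarse_tree(X, np.array([TWO] * 6))
        assert model.root.is_leaf
        assert model.root.prediction == TWO
        assert model.n_splits == 0

    def test_order_invariance(self, rng):
        X = rng.random((30, 2))
        y = np.where(X[:, 1] + 0.2 * rng.random(30) > 0.5, MULTI, TWO)
        base = fit_coarse_tree(X, y)
        perm = rng.permutation(30)
        shuffled = fit_coarse_tree(X[perm], y[perm])
        assert base.to_rules() == shuffled.to_rules()

    def test_max_four_splits(self, rng):
        X = rng.random((60, 2))
        y = np.where(rng.random(60) > 0.5, MULTI, TWO)  # unlearnable: grows deep
        model = fit_coarse_tree(X, y)
        assert model.n_splits <= 4

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_coarse_tree(np.array([[np.nan, 1.0]]), np.array([TWO]))


class TestPrintedRuleTree:
    """The fixture tree carries the published cutoffs: two modules when CRP
    asymmetry < 0.27 or CST asymmetry < -0.02 (features are (cst, crp))."""

    @pytest.mark.parametrize(
        "cst,crp,expected",
        [
            (0.50, 0.20, TWO),
            (-0.10, 0.50, TWO),
            (0.50, 0.50, MULTI),
            (-0.02, 0.27, MULTI),  # boundary: strict less-than
        ],
    )
    def test_probes(self, cst, crp, expected):
        assert predict_tree(printed_rule_tree(), (cst, crp)) == expected

    def test_missing_feature_raises(self):
        with pytest.raises(ValueError):
            predict_tree(printed_rule_tree(), (np.nan, 0.2))


class TestCrossValidate:
    def test_perfectly_separable_100pct(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.random((20, 2)), rng.random((20, 2)) + 2.0])
        y = np.array([TWO] * 20 + [MULTI] * 20)
        cv = cross_validate(X, y, seed=0)
        assert cv.accuracy_percent == 100.0
        assert cv.resubstitution_confusion.overall_percent == 100.0

    def test_deterministic(self, rng):
        X = rng.random((25, 2))
        y = np.where(X[:, 0] > 0.4, MULTI, TWO)
        a = cross_validate(X, y, seed=9)
        b = cross_validate(X, y, seed=9)
        assert a.accuracy_percent == b.accuracy_percent
        assert a.pooled_confusion.counts == b.pooled_confusion.counts

    def test_permuted_labels_near_chance(self, rng):
        """With labels shuffled, out-of-fold accuracy sits near the majority-
        class rate rather than near the resubstitution accuracy."""
        X = rng.random((60, 2))
        y = np.array([TWO] * 20 + [MULTI] * 40)
        rng.shuffle(y)
        cv = cross_validate(X, y, seed=1)
        majority = 100.0 * 40 / 60
        assert abs(cv.accuracy_percent - majority) < 25.0


class TestFMAClassifier:
    @pytest.mark.parametrize(
        "score,expected", [(14, TWO), (15, MULTI), (22, MULTI), (0, TWO)]
    )
    def test_cutoff(self, score, expected):
        assert fma_threshold_classifier(score) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            fma_threshold_classifier(23)


class TestConfusionReport:
    def test_printed_tree_counts(self):
        """28/30 and 7/13 correct give 93%, 53% and 81% overall under the
        truncating display convention."""
        true = [MULTI] * 30 + [TWO] * 13
        pred = [MULTI] * 28 + [TWO] * 2 + [TWO] * 7 + [MULTI] * 6
        c = confusion_report(true, pred)
        assert c.overall_percent == pytest.approx(100 * 35 / 43)
        assert c.display(c.per_class_percent(MULTI)) == 93
        assert c.display(c.per_class_percent(TWO)) == 53
        assert c.display(c.overall_percent) == 81

    def test_printed_fma_counts(self):
        true = [MULTI] * 30 + [TWO] * 13
        pred = [MULTI] * 24 + [TWO] * 6 + [TWO] * 10 + [MULTI] * 3
        c = confusion_report(true, pred)
        assert c.display(c.per_class_percent(TWO)) == 76
        assert c.display(c.per_class_percent(MULTI)) == 80
        assert c.display(c.overall_percent) == 79

    def test_all_correct(self):
        c = confusion_report([TWO, MULTI], [TWO, MULTI])
        assert c.overall_percent == 100.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_report([TWO], [])


class TestSubjectTable:
    def test_columns_and_consistency(self):
        subjects = synth.generate_cohort(20, 5, seed=2)
        table = cohort.subject_table(subjects)
        assert len(table) == 25
        stroke = table[table.group == "stroke"]
        assert set(stroke.pattern_class) <= {TWO, MULTI}
        # deviations consistent with pp
        assert np.allclose(stroke.pp_deviation, np.abs(stroke.pp - 0.5))
        two = stroke[stroke.k_true <= 2]
        assert (two.pattern_class == TWO).all()
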