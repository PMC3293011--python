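"""ROC/AUROC, exact intervals, operating points, serial testing, triage yield."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgtriage.evaluate import (ConfusionCounts, auroc, auroc_ci,
                                clopper_pearson, confusion, evaluate_cohort,
                                metrics, roc_points, serial_combine,
                                threshold_at_sensitivity,
                                transmission_reduction)


def _random_cohort(rng, n=60, sep=1.0, prev=0.3):
    y = rng.random(n) < prev
    if y.all() or not y.any():
        y[0], y[1] = True, False
    s = rng.normal(0, 1, n) + sep * y
    return s, y


def _pair_count_auroc(scores, labels):
    """All-pairs brute-force oracle: ties count one half."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation_reaches_corner(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([True, True, False, False])
        assert any(sens == 1.0 and spec == 1.0 for _, sens, spec in roc_points(s, y))

    def test_all_tied_scores_degenerate(self):
        s = np.full(6, 0.5)
        y = np.array([True, False] * 3)
        pts = roc_points(s, y)
        assert (0.0, 1.0) in {(sens, spec) for _, sens, spec in pts}
        assert (1.0, 0.0) in {(sens, spec) for _, sens, spec in pts}

    def test_points_match_brute_force_confusion(self):
        rng = np.random.default_rng(0)
        s, y = _random_cohort(rng)
        for thr, sens, spec in roc_points(s, y):
            called = s >= thr
            assert sens == pytest.approx((called & y).sum() / y.sum())
            assert spec == pytest.approx((~called & ~y).sum() / (~y).sum())

    def test_sensitivity_monotone_along_curve(self):
        rng = np.random.default_rng(1)
        s, y = _random_cohort(rng)
        sens = [p[1] for p in roc_points(s, y)]
        assert all(a <= b for a, b in zip(sens, sens[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_points(np.array([0.1, 0.2]), np.array([True, True]))


class TestAuroc:
    def test_perfect_separation(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([True, True, False, False])
        assert auroc(s, y) == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(2)
        s, y = _random_cohort(rng, n=4000, sep=0.0)
        assert auroc(s, y) == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pair_count_oracle_small(self, seed):
        rng = np.random.default_rng(seed)
        s, y = _random_cohort(rng, n=25)
        s = np.round(s, 1)                       # force ties
        assert auroc(s, y) == pytest.approx(_pair_count_auroc(s, y), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        s, y = _random_cohort(rng, n=200)
        assert auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestAurocCi:
    def test_perfect_separation_degenerate_interval(self):
        s = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.05])
        y = np.array([True] * 3 + [False] * 3)
        assert auroc_ci(s, y, n_boot=200, seed=0) == (1.0, 1.0)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        s, y = _random_cohort(rng)
        lo, hi = auroc_ci(s, y, n_boot=300, seed=1)
        assert lo <= auroc(s, y) <= hi

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        s1, y1 = _random_cohort(rng, n=100)
        s2, y2 = _random_cohort(rng, n=2000)
        w1 = np.diff(auroc_ci(s1, y1, n_boot=500, seed=2))[0]
        w2 = np.diff(auroc_ci(s2, y2, n_boot=500, seed=2))[0]
        assert w2 < w1

    def test_bootstrap_coverage_near_nominal(self):
        # Binormal model: positives N(mu, 1), negatives N(0, 1), so the true
        # AUROC is Phi(mu / sqrt(2)).
        from scipy.stats import norm
        mu = 1.0
        true_auc = norm.cdf(mu / np.sqrt(2))
        rng = np.random.default_rng(6)
        hits = 0
        reps = 500
        for rep in range(reps):
            s = np.concatenate([rng.normal(mu, 1, 30), rng.normal(0, 1, 50)])
            y = np.array([True] * 30 + [False] * 50)
            lo, hi = auroc_ci(s, y, n_boot=400, seed=rep)
            hits += lo <= true_auc <= hi
        assert hits / reps == pytest.approx(0.95, abs=0.03)


class TestOperatingPoint:
    def test_target_one_detects_every_positive(self):
        rng = np.random.default_rng(7)
        s, y = _random_cohort(rng)
        thr, achieved = threshold_at_sensitivity(s, y, 1.0)
        assert achieved == 1.0
        assert np.all(s[y] >= thr)

    def test_38_positives_at_95_percent(self):
        rng = np.random.default_rng(8)
        s = rng.random(560)
        y = np.zeros(560, bool)
        y[:38] = True
        _, achieved = threshold_at_sensitivity(s, y, 0.95)
        assert achieved >= 37 / 38          # ceil(0.95 * 38) = 37 detections

    def test_raising_target_never_raises_specificity(self):
        rng = np.random.default_rng(9)
        s, y = _random_cohort(rng, n=200)
        specs = []
        for target in (0.7, 0.8, 0.9, 0.95, 1.0):
            thr, _ = threshold_at_sensitivity(s, y, target)
            c = confusion(s, y, thr)
            specs.append(c.tn / (c.tn + c.fp))
        assert all(a >= b for a, b in zip(specs, specs[1:]))

    def test_maximizes_specificity_under_constraint(self):
        rng = np.random.default_rng(10)
        s, y = _random_cohort(rng, n=80)
        target = 0.9
        thr, _ = threshold_at_sensitivity(s, y, target)
        c = confusion(s, y, thr)
        best_spec = c.tn / (c.tn + c.fp)
        for cand in np.unique(s):           # exhaustive threshold scan
            cc = confusion(s, y, cand)
            if cc.tp / (cc.tp + cc.fn) >= target:
                assert cc.tn / (cc.tn + cc.fp) <= best_spec + 1e-12


class TestConfusion:
    def test_extreme_thresholds(self):
        rng = np.random.default_rng(11)
        s, y = _random_cohort(rng)
        hi = confusion(s, y, s.max() + 1)
        assert hi.tp == hi.fp == 0
        lo = confusion(s, y, s.min())
        assert lo.tn == lo.fn == 0

    def test_counts_sum_and_match_recount(self):
        rng = np.random.default_rng(12)
        s, y = _random_cohort(rng, n=150)
        thr = float(np.median(s))
        c = confusion(s, y, thr)
        assert c.n == 150
        assert c.tp == int(sum(1 for si, yi in zip(s, y) if si >= thr and yi))
        assert c.tn == int(sum(1 for si, yi in zip(s, y) if si < thr and not yi))


class TestClopperPearson:
    def test_boundary_cases(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_interval_contains_point_estimate(self):
        for k, n in [(0, 5), (3, 7), (36, 38), (50, 50)]:
            lo, hi = clopper_pearson(k, n)
            assert lo <= k / n <= hi

    def test_matches_statsmodels_exact_method(self):
        from statsmodels.stats.proportion import proportion_confint
        for k, n in [(2, 10), (36, 38), (35, 36), (17, 100), (0, 12), (9, 9)]:
            lo, hi = clopper_pearson(k, n, 0.95)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)
        with pytest.raises(ValueError):
            clopper_pearson(-1, 3)
        with pytest.raises(ValueError):
            clopper_pearson(1, 3, level=1.5)


class TestMetrics:
    def test_formula_oracle_on_random_counts(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 60, size=4)
            m = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert m["sens"].value == pytest.approx(tp / (tp + fn))
            assert m["spec"].value == pytest.approx(tn / (tn + fp))
            assert m["ppv"].value == pytest.approx(tp / (tp + fp))
            assert m["npv"].value == pytest.approx(tn / (tn + fn))

    def test_zero_denominator_reported_undefined(self):
        c = ConfusionCounts(tp=0, fp=0, tn=5, fn=3)
        with pytest.warns(UserWarning, match="undefined"):
            m = metrics(c)
        assert m["ppv"] is None
        assert m["spec"].value == 1.0


class TestSerialAndReduction:
    def test_all_positive_screen_passes_through(self):
        confirm = np.array([True, False, True])
        assert np.array_equal(serial_combine([True] * 3, confirm), confirm)

    def test_all_negative_screen_blocks_everything(self):
        assert not serial_combine([False] * 4, [True] * 4).any()

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 20 - 1), st.integers(0, 2 ** 20 - 1),
           st.integers(0, 2 ** 20 - 1))
    def test_dominance_inequalities(self, a_bits, b_bits, y_bits):
        n = 20
        screen = np.array([(a_bits >> i) & 1 for i in range(n)], bool)
        confirm = np.array([(b_bits >> i) & 1 for i in range(n)], bool)
        y = np.array([(y_bits >> i) & 1 for i in range(n)], bool)
        if not y.any() or y.all():
            return
        combined = serial_combine(screen, confirm)

        def sens(flags):
            return (flags & y).sum() / y.sum()

        def spec(flags):
            return (~flags & ~y).sum() / (~y).sum()

        assert sens(combined) <= min(sens(screen), sens(confirm)) + 1e-12
        assert spec(combined) >= max(spec(screen), spec(confirm)) - 1e-12

    def test_study_arithmetic_204_of_560(self):
        flags = np.zeros(560, bool)
        flags[:204] = True
        assert round(100 * transmission_reduction(flags)) == 64

    def test_extremes(self):
        assert transmission_reduction([True] * 5) == 0.0
        assert transmission_reduction([False] * 5) == 1.0
        with pytest.raises(ValueError):
            transmission_reduction([])


class TestReport:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(14)
        s, y = _random_cohort(rng, n=200, sep=2.0)
        rep = evaluate_cohort(s, y, target_sensitivity=0.9, n_boot=200, seed=0)
        assert rep.achieved_sensitivity >= 0.9
        assert rep.counts.n == 200
        assert 0 <= rep.reduction <= 1
        d = rep.to_dict()
        assert set(d["counts"]) == {"tp", "fp", "tn", "fn"}
        assert isinstance(rep.summary(), str) and "AUROC" in rep.summary()
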