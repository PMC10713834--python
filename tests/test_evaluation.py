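"""ROC/PR metrics, bootstrap CIs, DeLong, IDI/NRI, calibration, decision curves."""

import numpy as np
import pytest
from scipy.stats import norm

from dkihabitat.clinical_stats import mann_whitney_u
from dkihabitat.evaluation import (
    bootstrap_ci,
    calibration,
    confusion_metrics,
    decision_curve,
    delong_test,
    idi,
    nri,
    pr_auc,
    roc_auc,
)


class TestRocAuc:
    def test_labels_as_scores_give_one(self):
        assert roc_auc([0, 0, 1, 1, 1], [0, 0, 1, 1, 1]) == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        assert roc_auc([0.4] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_worked_three_quarters(self):
        assert roc_auc([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1]) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_u_over_n1n0(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(2, 30, size=2)
        scores = np.concatenate([rng.normal(1, 1, n1), rng.normal(0, 1, n0)])
        if seed % 4 == 0:
            scores = np.round(scores)  # force ties
        labels = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
        u = mann_whitney_u(scores[labels == 1], scores[labels == 0]).statistic
        assert roc_auc(scores, labels) == pytest.approx(u / (n1 * n0))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.uniform(size=40) < 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(a)
        assert roc_auc(np.tanh(scores / 3), labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestPrAuc:
    def test_perfect_scores(self):
        assert pr_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        labels = [0, 0, 0, 1, 1]
        assert pr_auc([0.5] * 5, labels) == pytest.approx(np.mean(labels))

    def test_four_point_worked_step_curve(self):
        # scores descending: 0.9(+), 0.7(-), 0.5(+), 0.3(-)
        # recall steps at the positives: P=1/1 at R=1/2, P=2/3 at R=2/2
        # area = 0.5*1 + 0.5*(2/3)
        expected = 0.5 * 1.0 + 0.5 * (2.0 / 3.0)
        assert pr_auc([0.9, 0.7, 0.5, 0.3], [1, 0, 1, 0]) == pytest.approx(expected)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.2, 0.4], [0, 0])


class TestBootstrap:
    def test_degenerate_metric_gives_zero_width(self):
        point, lo, hi = bootstrap_ci(
            [1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0], roc_auc, n_boot=200, seed=0
        )
        assert point == lo == hi == 1.0

    def test_ci_contains_point_estimate(self, rng):
        scores = rng.normal(size=80) + np.repeat([0, 1], 40)
        labels = np.repeat([0, 1], 40)
        point, lo, hi = bootstrap_ci(scores, labels, roc_auc, n_boot=300, seed=1)
        assert lo <= point <= hi

    def test_deterministic_given_seed(self, rng):
        scores = rng.normal(size=40)
        labels = np.repeat([0, 1], 20)
        assert bootstrap_ci(scores, labels, roc_auc, seed=5) == bootstrap_ci(
            scores, labels, roc_auc, seed=5
        )

    def test_coverage_of_true_auc(self):
        """95% interval covers the true AUC at close to nominal rate.

        Binormal scores with true AUC 0.8, 500 simulated datasets of n=100;
        coverage of the stratified percentile interval must land in [.92, .98].
        """
        mu = np.sqrt(2.0) * norm.ppf(0.8)
        rng = np.random.default_rng(42)
        hits = 0
        n_data = 500
        for _ in range(n_data):
            labels = np.repeat([0, 1], 50)
            scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(mu, 1, 50)])
            _, lo, hi = bootstrap_ci(
                scores, labels, roc_auc, n_boot=500, seed=int(rng.integers(2**31))
            )
            hits += lo <= 0.8 <= hi
        assert 0.92 <= hits / n_data <= 0.98

    def test_small_n_boot_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci(rng.normal(size=10), [0, 1] * 5, roc_auc, n_boot=50)


class TestConfusion:
    def test_perfect_probabilities(self):
        m = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert all(m[k].value == 1.0 for k in m)

    def test_threshold_zero(self):
        m = confusion_metrics([0.9, 0.1], [1, 0], 0.0)
        assert m["sensitivity"].value == 1.0
        assert m["specificity"].value == 0.0

    def test_worked_fractions(self):
        m = confusion_metrics([0.9, 0.6, 0.4, 0.1], [1, 1, 0, 0], 0.5)
        assert (m["sensitivity"].numerator, m["sensitivity"].denominator) == (2, 2)
        assert (m["specificity"].numerator, m["specificity"].denominator) == (2, 2)
        assert (m["accuracy"].numerator, m["accuracy"].denominator) == (4, 4)
        assert str(m["sensitivity"]) == "1.000 (2/2)"

    def test_sensitivity_monotone_in_threshold(self, rng):
        probs = rng.uniform(size=60)
        labels = (rng.uniform(size=60) < probs).astype(int)
        grid = np.linspace(0, 1, 21)
        sens = [confusion_metrics(probs, labels, t)["sensitivity"].value for t in grid]
        spec = [confusion_metrics(probs, labels, t)["specificity"].value for t in grid]
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(spec) >= -1e-12).all()


class TestDeLong:
    def test_identical_models_give_p_one(self, rng):
        scores = rng.normal(size=30)
        labels = np.repeat([0, 1], 15)
        auc_a, auc_b, p = delong_test(scores, scores, labels)
        assert auc_a == auc_b
        assert p == pytest.approx(1.0)

    def test_variance_matches_structural_components_by_hand(self):
        # 6 subjects: 3 positives, 3 negatives, two models
        a = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
        b = np.array([0.6, 0.9, 0.5, 0.4, 0.35, 0.1])
        y = np.array([1, 1, 1, 0, 0, 0])

        def components(s):
            pos, neg = s[y == 1], s[y == 0]
            psi = lambda x, v: 1.0 if x > v else (0.5 if x == v else 0.0)
            v10 = np.array([np.mean([psi(x, v) for v in neg]) for x in pos])
            v01 = np.array([np.mean([psi(x, v) for x in pos]) for v in neg])
            return v10.mean(), v10, v01

        auc_a, v10a, v01a = components(a)
        auc_b, v10b, v01b = components(b)
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 3 + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / 3
        z = (auc_a - auc_b) / np.sqrt(var)
        expected_p = 2 * norm.sf(abs(z))
        got_a, got_b, got_p = delong_test(a, b, y)
        assert (got_a, got_b) == pytest.approx((auc_a, auc_b))
        assert got_p == pytest.approx(expected_p)

    @pytest.mark.parametrize("seed", range(5))
    def test_close_to_paired_bootstrap_on_n60(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1], 30)
        a = rng.normal(size=60) + labels * 1.2
        b = 0.6 * a + rng.normal(size=60) * 0.8
        _, _, p_delong = delong_test(a, b, labels)
        idx_pos, idx_neg = np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)
        reps = np.empty(2000)
        brng = np.random.default_rng(seed + 1000)
        for k in range(2000):
            take = np.concatenate(
                [brng.choice(idx_pos, idx_pos.size), brng.choice(idx_neg, idx_neg.size)]
            )
            reps[k] = roc_auc(a[take], labels[take]) - roc_auc(b[take], labels[take])
        p_boot = min(1.0, 2 * min((reps <= 0).mean(), (reps >= 0).mean()))
        assert abs(p_delong - p_boot) < 0.05


class TestIdiNri:
    y8 = np.array([1, 1, 1, 1, 0, 0, 0, 0])

    def test_identical_models_give_zero(self, rng):
        p = rng.uniform(size=8)
        assert idi(p, p, self.y8, n_boot=100)[0] == pytest.approx(0.0)
        assert nri(p, p, self.y8, n_boot=100)[0] == pytest.approx(0.0)

    def test_idi_slope_formula(self):
        labels = np.array([1, 1, 0, 0])
        new = labels.astype(float)
        old = np.full(4, 0.5)
        assert idi(new, old, labels, n_boot=100)[0] == pytest.approx(1.0)

    def test_idi_matches_hand_computed_slopes(self):
        new = np.array([0.8, 0.7, 0.9, 0.6, 0.3, 0.2, 0.4, 0.35])
        old = np.array([0.6, 0.65, 0.7, 0.5, 0.45, 0.3, 0.5, 0.40])
        slope_new = new[self.y8 == 1].mean() - new[self.y8 == 0].mean()
        slope_old = old[self.y8 == 1].mean() - old[self.y8 == 0].mean()
        assert idi(new, old, self.y8, n_boot=100)[0] == pytest.approx(slope_new - slope_old)

    def test_nri_maximum_is_two(self):
        old = np.full(8, 0.5)
        new = np.where(self.y8 == 1, 0.9, 0.1)
        assert nri(new, old, self.y8, n_boot=100)[0] == pytest.approx(2.0)

    def test_nri_matches_exhaustive_counting(self):
        new = np.array([0.8, 0.4, 0.9, 0.6, 0.3, 0.6, 0.4, 0.35])
        old = np.array([0.6, 0.65, 0.9, 0.5, 0.45, 0.3, 0.5, 0.40])
        up = new > old
        down = new < old
        ev, ne = self.y8 == 1, self.y8 == 0
        expected = up[ev].mean() - down[ev].mean() + down[ne].mean() - up[ne].mean()
        assert nri(new, old, self.y8, n_boot=100)[0] == pytest.approx(expected)

    def test_categorical_nri_uses_cut_points(self):
        old = np.array([0.10, 0.30, 0.60, 0.55, 0.20, 0.80, 0.40, 0.45])
        new = old + np.array([0.15, 0.05, 0.2, -0.2, 0.05, -0.4, -0.05, 0.0])
        cuts = [0.25, 0.5]
        cat = lambda p: np.searchsorted(cuts, p, side="right")
        up = cat(new) > cat(old)
        down = cat(new) < cat(old)
        ev, ne = self.y8 == 1, self.y8 == 0
        expected = up[ev].mean() - down[ev].mean() + down[ne].mean() - up[ne].mean()
        got = nri(new, old, self.y8, categories=cuts, n_boot=100)[0]
        assert got == pytest.approx(expected)

    def test_antisymmetry(self, rng):
        new, old = rng.uniform(size=8), rng.uniform(size=8)
        assert idi(new, old, self.y8, n_boot=100)[0] == pytest.approx(
            -idi(old, new, self.y8, n_boot=100)[0]
        )
        assert nri(new, old, self.y8, n_boot=100)[0] == pytest.approx(
            -nri(old, new, self.y8, n_boot=100)[0]
        )


class TestCalibration:
    def test_perfect_probabilities_have_zero_brier(self):
        _, brier = calibration([1.0, 1.0, 0.0], [1, 1, 0])
        assert brier == 0.0

    def test_constant_half_has_quarter_brier(self):
        _, brier = calibration([0.5] * 10, [0, 1] * 5)
        assert brier == pytest.approx(0.25)

    def test_brier_decomposition_for_constant_predictor(self, rng):
        labels = (rng.uniform(size=200) < 0.3).astype(int)
        prev = labels.mean()
        for p_hat in (0.2, 0.5, 0.9):
            _, brier = calibration(np.full(200, p_hat), labels)
            assert brier == pytest.approx(p_hat**2 * (1 - prev) + (1 - p_hat) ** 2 * prev)

    def test_well_calibrated_model_has_small_bin_gaps(self):
        rng = np.random.default_rng(77)
        probs = rng.uniform(0.05, 0.95, size=2000)
        labels = (rng.uniform(size=2000) < probs).astype(int)
        bins, _ = calibration(probs, labels, n_bins=10)
        gaps = (bins["mean_predicted"] - bins["observed_rate"]).abs()
        assert gaps.max() < 0.1

    def test_equal_frequency_bins(self, rng):
        probs = rng.uniform(size=1000)
        bins, _ = calibration(probs, (rng.uniform(size=1000) < 0.5).astype(int))
        assert len(bins) == 10
        assert bins["n"].min() >= 90


class TestDecisionCurve:
    def test_treat_none_is_zero_everywhere(self, rng):
        probs = rng.uniform(size=40)
        labels = np.repeat([0, 1], 20)
        table = decision_curve(probs, labels)
        assert (table["treat_none"] == 0).all()

    def test_treat_all_tends_to_prevalence(self):
        probs = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        table = decision_curve(probs, labels, thresholds=[0.001, 0.5])
        assert table["treat_all"].iloc[0] == pytest.approx(0.5, abs=0.01)

    def test_worked_net_benefit_at_half(self):
        table = decision_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], thresholds=[0.5])
        assert table["net_benefit"].iloc[0] == pytest.approx(0.5)

    def test_perfect_predictor_matches_prevalence(self, rng):
        labels = np.repeat([0, 1], 25)
        probs = labels.astype(float)
        table = decision_curve(probs, labels)
        assert np.allclose(table["net_benefit"], labels.mean())

    def test_thresholds_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5, 0.6], [0, 1], thresholds=[0.0, 0.5])
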