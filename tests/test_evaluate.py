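"""ROC/AUC statistics: pair-counting oracle, CIs, cutoffs, design widths."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocims import (
    CVConfig,
    InputError,
    auc,
    auc_ci,
    auc_pvalue,
    build_report,
    ci_width_for_design,
    confusion_metrics,
    diagnostics_from_scores,
    flatten,
    hanley_mcneil_se,
    optimal_cutoff,
    rank_sum_pvalue,
    roc_curve,
    run_cv,
)


def pair_count_auc(scores, labels):
    """Brute-force over all (positive, negative) pairs (the AUC oracle)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (pos.size * neg.size)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_full_ties_give_half(self):
        assert auc([1, 2, 1, 2], [1, 1, 0, 0]) == 0.5

    def test_mixed_example_against_brute_force(self):
        scores = [3, 1, 2, 0]
        labels = [1, 1, 0, 0]
        assert auc(scores, labels) == 0.75 == pair_count_auc(scores, labels)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            auc([1, 2], [1, 1])

    @given(
        scores=st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_score_negation_complements_auc(self, scores):
        labels = np.arange(len(scores)) % 2
        s = np.asarray(scores)
        assert auc(s, labels) + auc(-s, labels) == pytest.approx(1.0)


class TestROCCurve:
    def test_perfect_separation_passes_through_corner(self):
        curve = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        pts = set(zip(curve.fpr.tolist(), curve.tpr.tolist()))
        assert (0.0, 1.0) in pts
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0

    def test_constant_scores_give_diagonal(self):
        curve = roc_curve([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert curve.area == pytest.approx(0.5)
        assert len(curve.fpr) == 2

    def test_monotone_rates(self):
        rng = np.random.default_rng(1)
        curve = roc_curve(rng.normal(size=50), rng.integers(0, 2, 50))
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_trapezoid_area_equals_pair_counting(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(10, 100)
            scores = np.round(rng.normal(size=n), 1)  # ties included
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_curve(scores, labels).area == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12
            )


class TestAUCConfidenceIntervals:
    def test_perfect_auc_has_zero_hanley_mcneil_width(self):
        lo, hi = auc_ci([1, 2, 3, 4], [0, 0, 1, 1], method="hanley_mcneil")
        assert (lo, hi) == (1.0, 1.0)

    def test_delong_matches_pROC_reference(self):
        # reference values computed once with R pROC (ci.auc, method="delong")
        rng = np.random.default_rng(42)
        neg = np.round(rng.normal(0, 1, 30), 6)
        pos = np.round(rng.normal(1.2, 1, 20), 6)
        scores = np.concatenate([neg, pos])
        labels = np.concatenate([np.zeros(30, int), np.ones(20, int)])
        assert auc(scores, labels) == pytest.approx(0.9066666667, abs=1e-9)
        lo, hi = auc_ci(scores, labels, method="delong")
        assert lo == pytest.approx(0.8268341714, abs=1e-9)
        assert hi == pytest.approx(0.9864991619, abs=1e-9)

    def test_delong_coverage_near_nominal(self):
        # binormal model with known population AUC; 400 seeded replicates
        from scipy.stats import norm

        target = 0.8
        mu = math.sqrt(2) * norm.ppf(target)  # binormal separation for this AUC
        rng = np.random.default_rng(7)
        labels = np.repeat([0, 1], 50)
        covered = 0
        reps = 400
        for _ in range(reps):
            scores = np.concatenate(
                [rng.normal(0, 1, 50), rng.normal(mu, 1, 50)]
            )
            lo, hi = auc_ci(scores, labels, method="delong")
            covered += lo <= target <= hi
        assert 0.90 <= covered / reps <= 0.985

    def test_delong_and_hanley_mcneil_agree_on_balanced_data(self):
        from scipy.stats import norm

        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 60)
        for target in (0.6, 0.75, 0.9):
            mu = math.sqrt(2) * norm.ppf(target)
            scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(mu, 1, 60)])
            dl, dh = auc_ci(scores, labels, method="delong")
            hl, hh = auc_ci(scores, labels, method="hanley_mcneil")
            assert (hh - hl) == pytest.approx(dh - dl, rel=0.2)


class TestDesignWidth:
    def test_reference_design_width(self):
        # 123 cases vs 62 controls at AUC 0.87 -> CI width 0.10
        assert round(ci_width_for_design(0.87, 123, 62), 2) == 0.10

    def test_width_shrinks_as_sqrt_n(self):
        w1 = ci_width_for_design(0.8, 60, 40)
        w2 = ci_width_for_design(0.8, 120, 80)
        assert w2 == pytest.approx(w1 / math.sqrt(2), rel=0.05)

    def test_width_vanishes_as_auc_approaches_one(self):
        assert ci_width_for_design(0.9999, 50, 50) < 1e-2

    def test_strictly_decreasing_in_each_group_size(self):
        widths_pos = [ci_width_for_design(0.8, n, 50) for n in (10, 20, 40, 80, 160)]
        widths_neg = [ci_width_for_design(0.8, 50, n) for n in (10, 20, 40, 80, 160)]
        assert all(a > b for a, b in zip(widths_pos, widths_pos[1:]))
        assert all(a > b for a, b in zip(widths_neg, widths_neg[1:]))

    def test_design_auc_domain_enforced(self):
        with pytest.raises(InputError):
            ci_width_for_design(0.4, 50, 50)
        with pytest.raises(InputError):
            ci_width_for_design(1.0, 50, 50)

    def test_group_order_matters_for_unbalanced_designs(self):
        assert ci_width_for_design(0.87, 123, 62) != pytest.approx(
            ci_width_for_design(0.87, 62, 123), rel=1e-3
        )


class TestAUCPValue:
    def test_exact_small_sample_example(self):
        assert auc_pvalue([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(1 / 3)

    def test_identical_score_multisets_give_p_one(self):
        assert auc_pvalue([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_matches_rank_sum_on_same_split(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        labels = rng.permutation(np.repeat([0, 1], 20))
        assert auc_pvalue(scores, labels) == rank_sum_pvalue(
            scores[labels == 1], scores[labels == 0]
        )


class TestOptimalCutoff:
    @staticmethod
    def brute_force(scores, labels):
        """Scan every candidate cutoff (each score and +inf) for max J."""
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        rows = []
        for c in np.concatenate([[np.inf], np.unique(scores)[::-1]]):
            sens, spec, _, _ = confusion_metrics(scores, labels, c)
            rows.append((c, sens, spec, sens + spec - 1))
        jmax = max(r[3] for r in rows)
        tied = [r for r in rows if r[3] >= jmax - 1e-9]
        c, sens, spec, _ = sorted(tied, key=lambda r: (-r[2], r[0]))[0]
        return c, sens, spec

    def test_perfect_separation_reaches_j_one(self):
        curve = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        _, sens, spec = optimal_cutoff(curve)
        assert sens == 1.0 and spec == 1.0

    def test_constant_scores_give_j_zero(self):
        curve = roc_curve([0.5] * 6, [0, 1, 0, 1, 0, 1])
        _, sens, spec = optimal_cutoff(curve)
        assert sens + spec == pytest.approx(1.0)

    def test_against_exhaustive_scan_oracle(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0, 0]
        got = optimal_cutoff(roc_curve(scores, labels))
        want = self.brute_force(scores, labels)
        assert got[1:] == pytest.approx(want[1:])
        sens, spec, _, _ = confusion_metrics(scores, labels, got[0])
        assert (sens, spec) == pytest.approx((got[1], got[2]))

    def test_random_sets_match_oracle_J(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            scores = np.round(rng.uniform(size=12), 1)
            labels = rng.permutation(np.repeat([0, 1], 6))
            _, sens, spec = optimal_cutoff(roc_curve(scores, labels))
            _, osens, ospec = self.brute_force(scores, labels)
            assert sens + spec == pytest.approx(osens + ospec, abs=1e-12)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5)
        assert m == (1.0, 1.0, 1.0, 1.0)

    def test_cutoff_below_all_scores(self):
        scores = [0.3, 0.4, 0.6, 0.7, 0.8]
        labels = [0, 0, 1, 1, 1]
        sens, spec, ppv, npv = confusion_metrics(scores, labels, 0.0)
        assert sens == 1.0 and spec == 0.0
        assert ppv == pytest.approx(3 / 5)  # prevalence
        assert math.isnan(npv)  # no negative predictions -> undefined, not 0

    def test_hand_computed_counts(self):
        # 100 positives: 59 above cutoff; 100 negatives: 23 above cutoff
        scores = np.concatenate(
            [np.full(59, 0.9), np.full(41, 0.1), np.full(23, 0.9), np.full(77, 0.1)]
        )
        labels = np.concatenate([np.ones(100, int), np.zeros(100, int)])
        sens, spec, ppv, npv = confusion_metrics(scores, labels, 0.5)
        assert sens == pytest.approx(59 / 100)
        assert spec == pytest.approx(77 / 100)
        assert ppv == pytest.approx(59 / 82)
        assert npv == pytest.approx(77 / 118)


class TestReport:
    def test_invariants_on_simulated_cohort(self, small_cohort):
        table = flatten(small_cohort)
        res = run_cv(table, CVConfig(k=3, n_top_features=20, seed=0))
        rep = build_report(res, table.labels)
        assert 0.0 <= rep.auc <= 1.0
        assert rep.ci_low <= rep.auc <= rep.ci_high
        for rate in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert 0.0 <= rate <= 1.0 or math.isnan(rate)
        assert rep.n_pos == 6 and rep.n_neg == 6

    def test_strong_effect_detected(self, small_cohort):
        table = flatten(small_cohort)
        res = run_cv(table, CVConfig(k=3, n_top_features=20, seed=0))
        rep = build_report(res, table.labels)
        assert rep.auc > 0.9
        assert rep.p_value < 0.01

    def test_report_from_scores_round_trips_to_dict(self):
        rep = diagnostics_from_scores([0.1, 0.9, 0.2, 0.8], [0, 1, 0, 1])
        d = rep.to_dict()
        assert d["auc"] == 1.0 and d["n_pos"] == 2


def test_hanley_mcneil_se_closed_form_value():
    # direct evaluation: A=0.87, 123 cases, 62 controls
    se = hanley_mcneil_se(0.87, 123, 62)
    assert 2 * 1.959963985 * se == pytest.approx(0.0995, abs=5e-4)
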