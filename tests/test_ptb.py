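import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestage import (
    SyntheticConfig,
    classification_metrics,
    classify_ptb,
    fisher_pairwise,
    generate_cohort,
    jaccard,
    jaccard_matrix,
    ptb_rate,
    ptb_report,
    truth_table,
)
from gestage.errors import ValidationError


class TestClassify:
    def test_36w6d_is_preterm(self):
        assert classify_ptb(36.857) is True

    def test_boundary_37_is_term(self):
        assert classify_ptb(37.0) is False

    def test_39_is_term(self):
        assert classify_ptb(39.0) is False

    def test_vectorized(self):
        flags = classify_ptb([30.0, 37.0, 40.0])
        assert flags.tolist() == [True, False, False]

    @pytest.mark.parametrize("bad", [-1.0, 55.0, np.nan])
    def test_invalid_ga_rejected(self, bad):
        with pytest.raises(ValidationError):
            classify_ptb(bad)


class TestRate:
    def test_table1_training_counts(self):
        flags = [True] * 251 + [False] * (1510 - 251)
        res = ptb_rate(flags)
        assert round(res.rate, 2) == 16.62

    def test_zero_events(self):
        res = ptb_rate([False] * 10)
        assert res.rate == 0.0
        assert res.ci_lower == 0.0

    def test_wilson_hand_computed(self):
        # k=1, n=4: Wilson closed form with z=1.959964
        res = ptb_rate([True, False, False, False])
        z = 1.959963984540054
        p, n = 0.25, 4
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (
            z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        )
        assert res.rate == pytest.approx(25.0)
        assert res.ci_lower == pytest.approx(100 * (centre - half), abs=1e-6)
        assert res.ci_upper == pytest.approx(100 * (centre + half), abs=1e-6)

    def test_clopper_pearson_flag(self):
        res = ptb_rate([True, False, False, False], ci_method="beta")
        # exact CP for k=1, n=4: lower = 1 - (0.975)^(1/4) ... use scipy beta
        from scipy.stats import beta

        lo = beta.ppf(0.025, 1, 4)
        hi = beta.ppf(0.975, 2, 3)
        assert res.ci_lower == pytest.approx(100 * lo, abs=1e-6)
        assert res.ci_upper == pytest.approx(100 * hi, abs=1e-6)

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            ptb_rate([])

    def test_wilson_coverage_simulation(self):
        """~95% empirical coverage at p=0.14, n=1500 over 10^4 draws."""
        rng = np.random.default_rng(0)
        p, n, sims = 0.14, 1500, 10_000
        ks = rng.binomial(n, p, size=sims)
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(ks, n, alpha=0.05, method="wilson")
        coverage = np.mean((lo <= p) & (p <= hi))
        assert 0.94 <= coverage <= 0.96


class TestFisher:
    def test_identical_counts_p_one(self):
        mat = fisher_pairwise([10, 10], [100, 100])
        assert mat.iloc[0, 1] == 1.0

    def test_hand_enumerated_table(self):
        """2x2 table (1,9 / 11,3): two-sided p from hypergeometric
        enumeration (oracle) matches the implementation (no correction)."""
        from scipy.stats import hypergeom

        k1, n1, k2, n2 = 1, 10, 11, 14
        K, N = k1 + k2, n1 + n2
        rv = hypergeom(N, K, n1)
        p_obs = rv.pmf(k1)
        oracle = sum(rv.pmf(x) for x in range(0, min(K, n1) + 1)
                     if rv.pmf(x) <= p_obs + 1e-12)
        mat = fisher_pairwise([k1, k2], [n1, n2], correction="none")
        assert mat.iloc[0, 1] == pytest.approx(oracle, rel=1e-6)
        assert mat.iloc[0, 1] == pytest.approx(0.002759, abs=5e-5)

    def test_bonferroni_multiplies_by_pairs(self):
        raw = fisher_pairwise([5, 20, 5], [100, 100, 100], correction="none")
        adj = fisher_pairwise([5, 20, 5], [100, 100, 100])
        m_pairs = 3
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert adj.iloc[i, j] == pytest.approx(
                min(1.0, m_pairs * raw.iloc[i, j])
            )

    def test_pvalues_in_unit_interval(self):
        mat = fisher_pairwise([0, 50, 14], [100, 100, 100])
        vals = mat.to_numpy()
        assert np.all(vals > 0) and np.all(vals <= 1)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            fisher_pairwise([0, 1], [0, 10])

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_pairwise([11, 1], [10, 10])


class TestJaccard:
    def test_equal_nonempty(self):
        assert jaccard({1, 2}, {1, 2}) == 1.0

    def test_disjoint(self):
        assert jaccard({1}, {2}) == 0.0

    def test_hand_enumerated(self):
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_both_empty_defined_as_one(self):
        assert jaccard(set(), set()) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_symmetry_and_range(self, a, b):
        v = jaccard(a, b)
        assert v == jaccard(b, a)
        assert 0.0 <= v <= 1.0

    def test_matrix_symmetric_unit_diagonal(self):
        mat = jaccard_matrix({"a": {1, 2}, "b": {2, 3}, "c": set()})
        arr = mat.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)


class TestMetrics:
    def test_perfect_prediction(self):
        m = classification_metrics([1, 0, 1], [1, 0, 1])
        assert (m.sensitivity, m.specificity, m.balanced_accuracy) == (1, 1, 1)

    def test_all_term_prediction(self):
        ref = [1, 0, 0, 1, 0]
        m = classification_metrics([0] * 5, ref)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.balanced_accuracy == 0.5

    def test_hand_confusion(self):
        pred = [1] * 8 + [0] * 2 + [1] * 1 + [0] * 9
        ref = [1] * 10 + [0] * 10
        m = classification_metrics(pred, ref)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.9)
        assert m.balanced_accuracy == pytest.approx(0.85)

    def test_single_class_reference_flagged(self):
        m = classification_metrics([1, 0], [1, 1])
        assert math.isnan(m.specificity)
        assert "specificity_undefined" in m.flags


@pytest.fixture(scope="module")
def report_cohort():
    return generate_cohort(SyntheticConfig(n_participants=600, seed=31))


class TestReport:
    @pytest.fixture()
    def cohort(self, report_cohort):
        return report_cohort

    def test_method_vs_identical_alias(self, cohort):
        from gestage.formulae import register_from_dict, unregister_formula

        register_from_dict(
            {
                "id": "_test_same_as_garbhini",
                "expression": "-0.02294*crl**2 + 1.15018*crl + 6.73526",
                "valid_crl_range": [0.0, 10.0],
            }
        )
        try:
            report = ptb_report(
                cohort, ["garbhini_ga1", "_test_same_as_garbhini"], reference=None
            )
            assert report.jaccard.iloc[0, 1] == 1.0
            assert report.fisher_p.iloc[0, 1] == 1.0
        finally:
            unregister_formula("_test_same_as_garbhini")

    def test_offset_methods_monotone_counts(self, cohort):
        from gestage.formulae import register_from_dict, unregister_formula

        register_from_dict(
            {
                "id": "_test_plus_half_week",
                "expression": "-0.02294*crl**2 + 1.15018*crl + 7.23526",
                "valid_crl_range": [0.0, 10.0],
            }
        )
        try:
            report = ptb_report(cohort, ["garbhini_ga1", "_test_plus_half_week"])
            k_base = report.rates["garbhini_ga1"].k
            k_higher = report.rates["_test_plus_half_week"].k
            assert k_higher <= k_base
        finally:
            unregister_formula("_test_plus_half_week")

    def test_missing_outcomes_dropped_and_counted(self):
        cfg = SyntheticConfig(n_participants=300, seed=32, missing_outcome_frac=0.2)
        cohort = generate_cohort(cfg)
        report = ptb_report(cohort, ["garbhini_ga1", "lmp"])
        assert report.n_dropped_missing > 0
        assert report.rates["garbhini_ga1"].n == 300 - report.n_dropped_missing

    def test_reference_must_be_explicit(self, cohort):
        with pytest.raises(ValueError):
            ptb_report(cohort, ["garbhini_ga1", "lmp"], reference="hadlock")

    def test_truth_reference_metrics(self):
        cfg = SyntheticConfig(n_participants=800, seed=33)
        cohort = generate_cohort(cfg)
        truth = truth_table(cfg, cohort)
        ref = truth.participants.set_index("participant_id")["true_preterm"]
        report = ptb_report(cohort, ["garbhini_ga1", "lmp"], reference=ref)
        assert set(report.metrics) == {"garbhini_ga1", "lmp"}
        # truth-formula dating tracks true delivery GA far better than a
        # noisy, biased LMP recall
        assert (
            report.metrics["garbhini_ga1"].balanced_accuracy
            > report.metrics["lmp"].balanced_accuracy
        )

    def test_truth_formula_beats_biased_comparator_sensitivity(self):
        """Planted-bias comparator (+0.5 wk) misses preterm cases that the
        truth formula catches."""
        from gestage.formulae import register_from_dict, unregister_formula

        cfg = SyntheticConfig(n_participants=800, seed=34)
        cohort = generate_cohort(cfg)
        truth = truth_table(cfg, cohort)
        ref = truth.participants.set_index("participant_id")["true_preterm"]
        register_from_dict(
            {
                "id": "_test_biased_up",
                "expression": "-0.02294*crl**2 + 1.15018*crl + 7.23526",
                "valid_crl_range": [0.0, 10.0],
            }
        )
        try:
            report = ptb_report(cohort, ["garbhini_ga1", "_test_biased_up"],
                                reference=ref)
            assert (
                report.metrics["garbhini_ga1"].sensitivity
                >= report.metrics["_test_biased_up"].sensitivity
            )
        finally:
            unregister_formula("_test_biased_up")

    def test_identical_assignments_agree_exactly(self, cohort):
        report = ptb_report(cohort, ["garbhini_ga1", "hadlock", "lmp"])
        for m in report.rates.values():
            assert 0.0 <= m.rate <= 100.0
        arr = report.jaccard.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)

    def test_report_dict_serializable(self, cohort):
        import json

        report = ptb_report(cohort, ["garbhini_ga1", "lmp"], reference="lmp")
        payload = json.dumps(report.to_dict())
        assert "rate_per_100" in payload
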