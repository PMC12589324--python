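"""Gated comparisons, categorical associations, and the cohort report."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import fisher_two_sided_enum
from petirae.simulate import simulate_tabular_cohort
from petirae.stats import (
    PatientRecord,
    ReportConfig,
    build_cohort_report,
    categorical_assoc,
    contingency_compare,
    group_compare,
    lab_compare,
    median_split_association,
    paired_compare,
)


class TestPairedCompare:
    def test_constant_shift_with_jitter_selects_paired_t(self, rng):
        pre = rng.normal(2.0, 0.5, 30)
        post = pre + 1.0 + rng.normal(0, 0.05, 30)
        res = paired_compare(pre, post)
        assert res.test_name == "paired_t" and res.normality_gate
        # closed-form paired t: t = mean(d)/(sd(d)/sqrt(n)), p = 2*sf(|t|, n-1)
        d = post - pre
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t), len(d) - 1)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_heavy_tailed_differences_select_wilcoxon(self):
        picks = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            pre = r.normal(0, 1, 50)
            post = pre + r.standard_cauchy(50)
            picks += paired_compare(pre, post).test_name == "wilcoxon_signed_rank"
        assert picks >= 90

    def test_identical_vectors_flagged_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_compare(x, x)
        assert res.degenerate and math.isnan(res.p_value)
        res2 = paired_compare(x, x + 2.0)  # constant nonzero difference
        assert res2.degenerate

    def test_length_mismatch_and_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            paired_compare([1, 2], [2, 3])


class TestGroupCompare:
    def test_symmetric_distinct_groups_give_t_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = group_compare(a, a[::-1].copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_identical_constant_groups_degenerate(self):
        res = group_compare([2.0] * 5, [2.0] * 5)
        assert res.degenerate

    def test_normal_shift_selects_student_t(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        res = group_compare(a, b)
        assert res.test_name == "student_t" and res.normality_gate
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_skewed_group_fails_gate_and_uses_mann_whitney(self, rng):
        a = rng.lognormal(0, 1.5, 40)
        b = rng.normal(1, 1, 40)
        res = group_compare(a, b)
        assert res.test_name == "mann_whitney_u" and not res.normality_gate

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCategoricalAssoc:
    def test_fisher_branch_with_enumeration_oracle(self):
        # min expected cell of this table is 32*11/64 = 5.5, so the auto rule
        # picks chi-square; the Fisher branch is checked explicitly.
        res = categorical_assoc([[10, 22], [1, 31]], test="fisher")
        assert res.test_used == "fisher_exact"
        assert res.odds_ratio == pytest.approx(310 / 22)
        assert res.p_value == pytest.approx(fisher_two_sided_enum(10, 22, 1, 31), abs=1e-12)
        # a genuinely sparse table triggers Fisher automatically
        auto = categorical_assoc([[8, 24], [1, 31]])
        assert auto.test_used == "fisher_exact"
        assert auto.p_value == pytest.approx(fisher_two_sided_enum(8, 24, 1, 31), abs=1e-12)

    def test_balanced_table_is_independent(self):
        for k in (3, 10):
            res = categorical_assoc([[k, k], [k, k]])
            assert res.odds_ratio == pytest.approx(1.0)
            assert res.p_value == pytest.approx(1.0)

    def test_zero_cells_get_haldane_correction(self):
        res = categorical_assoc([[5, 0], [0, 5]])
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))
        assert math.isfinite(res.odds_ratio)
        assert res.p_value == pytest.approx(fisher_two_sided_enum(5, 0, 0, 5), abs=1e-12)
        # a zero in a or d keeps the plain (defined) ratio 0
        res0 = categorical_assoc([[0, 5], [5, 5]])
        assert not res0.haldane_corrected and res0.odds_ratio == 0.0

    def test_large_expected_counts_use_chi_square(self):
        res = categorical_assoc([[30, 20], [18, 32]])
        assert res.test_used == "chi_square"
        assert res.p_value == pytest.approx(
            float(sps.chi2_contingency([[30, 20], [18, 32]])[1])
        )

    def test_odds_ratio_transpose_invariant_and_row_swap_inverts(self, rng):
        for _ in range(20):
            t = rng.integers(1, 30, (2, 2))
            orx = categorical_assoc(t).odds_ratio
            assert categorical_assoc(t.T).odds_ratio == pytest.approx(orx)
            assert categorical_assoc(t[::-1].copy()).odds_ratio == pytest.approx(1 / orx)

    def test_conditional_mle_estimator_available(self):
        res = categorical_assoc([[10, 22], [1, 31]], or_estimator="conditional_mle")
        assert res.odds_ratio == pytest.approx(
            float(sps.contingency.odds_ratio([[10, 22], [1, 31]]).statistic)
        )

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            categorical_assoc([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            categorical_assoc([[1.5, 2], [3, 4]])

    def test_empty_margin_degenerate(self):
        res = categorical_assoc([[0, 0], [3, 4]])
        assert res.degenerate and res.p_value == 1.0


class TestMedianSplit:
    def test_perfect_separation(self):
        res = median_split_association([1, 2, 3, 4], [0, 0, 1, 1])
        np.testing.assert_array_equal(res.table, [[2, 0], [0, 2]])
        assert res.tie_count == 0  # median 2.5 not attained

    def test_even_cohort_with_distinct_deltas_splits_evenly(self, rng):
        d = rng.normal(0, 1, 20)
        labels = rng.integers(0, 2, 20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        res = median_split_association(d, labels)
        assert res.table[0].sum() == 10 and res.table[1].sum() == 10

    def test_all_identical_deltas_degenerate(self):
        res = median_split_association([1.0] * 6, [0, 1, 0, 1, 0, 1])
        assert res.degenerate

    def test_ties_at_median_counted_and_fall_low(self):
        res = median_split_association([1, 2, 2, 2, 3, 4], [0, 0, 0, 1, 1, 1])
        assert res.tie_count == 3
        assert res.table[0].sum() == 2  # only the strict exceeders

    def test_zero_split_alternative(self):
        res = median_split_association([-1, -2, 1, 2], [0, 0, 1, 1], split="zero")
        np.testing.assert_array_equal(res.table, [[2, 0], [0, 2]])

    def test_label_requirements(self):
        with pytest.raises(ValueError):
            median_split_association([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            median_split_association([1, 2, 3], [0, 1, 0])

    def test_independent_labels_give_log_or_centered_at_zero(self):
        logs = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            d = r.normal(0, 1, 40)
            y = r.integers(0, 2, 40)
            if y.sum() in (0, 40):
                continue
            res = median_split_association(d, y)
            if res.odds_ratio > 0:
                logs.append(math.log(res.odds_ratio))
        mean = np.mean(logs)
        se = np.std(logs, ddof=1) / math.sqrt(len(logs))
        assert abs(mean) < 3.5 * se


class TestLabCompare:
    def test_no_missing_equals_paired_compare(self, rng):
        pre = rng.normal(1.2, 0.3, 27)
        post = pre - 0.12 + rng.normal(0, 0.2, 27)
        a = lab_compare(pre, post)
        b = paired_compare(pre, post)
        assert a.test_name == b.test_name
        assert a.p_value == pytest.approx(b.p_value)
        assert a.n == 27

    def test_missing_values_reduce_n_to_complete_cases(self, rng):
        pre = rng.normal(3.0, 0.5, 20)
        post = pre - 0.8 + rng.normal(0, 0.3, 20)
        pre[::2] = np.nan
        res = lab_compare(pre, post)
        assert res.n == 10

    def test_insufficient_pairs_flagged(self):
        res = lab_compare([1.0, np.nan, 2.0], [1.1, 2.0, np.nan])
        assert res.degenerate and "insufficient" in res.note


class TestPatientRecord:
    def test_subtype_requires_composite(self):
        with pytest.raises(ValueError, match="composite"):
            PatientRecord(
                patient_id="P", age=60, sex="male", cancer_type="lung",
                ici_drug="pembrolizumab", ici_class="PD-1",
                adverse_events=frozenset({"hypothyroidism"}),
            )

    def test_none_exclusive(self):
        with pytest.raises(ValueError, match="exclusive"):
            PatientRecord(
                patient_id="P", age=60, sex="male", cancer_type="lung",
                ici_drug="pembrolizumab", ici_class="PD-1",
                adverse_events=frozenset({"none", "colitis"}),
            )


class TestCohortReport:
    def test_thyroid_effect_cohort_flags_thyroid_rows(self):
        records, meas, deltas = simulate_tabular_cohort(seed=11)
        rep = build_cohort_report(records, meas, deltas, ReportConfig())
        ms = rep["median_split"]
        row = ms[(ms.ae_label == "thyroid_related") & (ms.organ == "thyroid")].iloc[0]
        assert row.odds_ratio > 1
        ae = rep["ae_group"]
        row = ae[
            (ae.ae_label == "thyroid_related")
            & (ae.organ == "thyroid")
            & (ae.statistic == "delta_suv_max")
        ].iloc[0]
        assert row.p_value < 0.05 and row.mean_pos > row.mean_neg

    def test_single_patient_cohort_yields_flagged_rows_not_errors(self):
        records, meas, deltas = simulate_tabular_cohort(seed=1)
        one = records.iloc[:1]
        meas1 = meas[meas.patient_id == one.patient_id.iloc[0]]
        deltas1 = deltas[deltas.patient_id == one.patient_id.iloc[0]]
        rep = build_cohort_report(one, meas1, deltas1, ReportConfig())
        assert rep["organ_paired"]["degenerate"].all()

    def test_unknown_patient_keys_reported_as_warnings(self):
        records, meas, deltas = simulate_tabular_cohort(seed=2)
        rep = build_cohort_report(records.iloc[:-1], meas, deltas, ReportConfig())
        assert (rep["warnings"]["context"] == "keys").any()

    def test_fdr_column_present_when_enabled(self):
        records, meas, deltas = simulate_tabular_cohort(seed=3)
        rep = build_cohort_report(records, meas, deltas, ReportConfig(fdr_adjust=True))
        assert "p_adjusted_bh" in rep["organ_paired"].columns
        ok = rep["organ_paired"].dropna(subset=["p_value", "p_adjusted_bh"])
        assert (ok["p_adjusted_bh"] >= ok["p_value"] - 1e-12).all()

    def test_spleen_liver_ratio_row_present(self):
        records, meas, deltas = simulate_tabular_cohort(seed=4)
        rep = build_cohort_report(records, meas, deltas, ReportConfig())
        assert (rep["organ_paired"]["organ"] == "spleen_liver_ratio").any()


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=40), min_size=4, max_size=4))
def test_odds_ratio_symmetries_hold_for_any_positive_table(cells):
    a, b, c, d = cells
    t = np.array([[a, b], [c, d]])
    orx = categorical_assoc(t).odds_ratio
    assert categorical_assoc(t.T).odds_ratio == pytest.approx(orx)
    assert categorical_assoc(t[::-1].copy()).odds_ratio == pytest.approx(1 / orx)
    assert categorical_assoc(t[:, ::-1].copy()).odds_ratio == pytest.approx(1 / orx)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=5, max_size=30
    ),
    st.floats(min_value=-10, max_value=10, allow_nan=False),
)
def test_median_split_halves_never_exceed_half_plus_ties(deltas, jitter):
    deltas = np.asarray(deltas) + jitter
    labels = np.zeros(len(deltas), dtype=int)
    labels[0] = 1
    if np.ptp(deltas) == 0:
        return
    res = median_split_association(deltas, labels)
    n = len(deltas)
    # strictly-above-median group can never hold more than half the cohort
    assert res.table[0].sum() <= n // 2
    assert res.table.sum() == n


def test_contingency_compare_rxc_branch():
    groups = [0, 0, 0, 1, 1, 1] * 10
    values = (["a", "b", "c"] * 20)[:60]
    res = contingency_compare(groups, values)
    assert res.test_name == "chi_square_rxc"
    assert 0 <= res.p_value <= 1
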