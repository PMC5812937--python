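"""Expression-ratio table, group summaries, binomial and variance tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import homeologdiv as hd
from homeologdiv.ratios import (adjusted_binomial_pvalue, classify_balance,
                                summarize_group, summarize_ratio_table)


def _design(reps=2):
    rows = []
    for cond in ("control", "stress"):
        for tp in ("t18",):
            for rep in range(1, reps + 1):
                rows.append({"sample_id": f"{cond}_{tp}_r{rep}",
                             "condition": cond, "timepoint": tp,
                             "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id")


class TestRatioTable:
    def test_equal_rpkm_gives_half_balanced(self):
        design = _design()
        rpkm = pd.DataFrame(7.3, index=["g_A", "g_B"], columns=design.index)
        rt = hd.build_ratio_table(rpkm, design, [("g_A", "g_B")])
        assert (rt.table.ratio == 0.5).all()
        assert (rt.table.balance == "balanced").all()

    def test_silent_b_member_gives_ratio_one(self):
        design = _design()
        rpkm = pd.DataFrame({s: [12.0, 0.0] for s in design.index},
                            index=["g_A", "g_B"])
        rt = hd.build_ratio_table(rpkm, design, [("g_A", "g_B")])
        assert (rt.table.ratio == 1.0).all()
        assert (rt.table.balance == "unbalanced_A").all()

    def test_group_with_both_zero_is_undefined_but_pair_retained(self):
        design = _design()
        rpkm = pd.DataFrame(0.0, index=["g_A", "g_B"], columns=design.index)
        stress = design.index[design.condition == "stress"]
        rpkm.loc["g_A", stress] = 4.0
        rt = hd.build_ratio_table(rpkm, design, [("g_A", "g_B")])
        by_cond = rt.table.set_index("condition")
        assert np.isnan(by_cond.loc["control", "ratio"])
        assert by_cond.loc["control", "balance"] == "undefined"
        assert by_cond.loc["stress", "ratio"] == 1.0

    def test_unknown_gene_rejected(self):
        design = _design()
        rpkm = pd.DataFrame(1.0, index=["g_A"], columns=design.index)
        with pytest.raises(ValueError):
            hd.build_ratio_table(rpkm, design, [("g_A", "missing_B")])

    def test_no_evidence_pairs_dropped_entirely(self):
        design = _design()
        rpkm = pd.DataFrame(1.0, index=["g_A", "g_B", "h_A", "h_B"],
                            columns=design.index)
        evidence = pd.DataFrame(
            {"expressed_control": [True, False, False, False],
             "expressed_stress": [True, False, False, False]},
            index=rpkm.index)
        evidence["category"] = "unused"
        rt = hd.build_ratio_table(rpkm, design, [("g_A", "g_B"),
                                                 ("h_A", "h_B")],
                                  evidence=evidence)
        assert rt.n_pairs_excluded_no_evidence == 1
        assert rt.n_pairs_single_expressed == 1
        assert set(rt.table.pair_id) == {"PAIR00001"}

    def test_complement_pair_ratios_sum_to_one(self, small_catalogue,
                                               normalized, design):
        rt = hd.build_ratio_table(normalized.rpkm, design.samples(),
                                  small_catalogue.pairs)
        flipped = [(b, a) for a, b in small_catalogue.pairs]
        # swapped pair orientation on the same matrix mirrors every ratio
        rpkm_relab = normalized.rpkm
        rt_flip = hd.build_ratio_table(rpkm_relab, design.samples(), flipped)
        s = rt.table.ratio.values + rt_flip.table.ratio.values
        defined = ~np.isnan(s)
        assert np.all(s[defined] == 1.0)

    def test_global_rescaling_leaves_table_unchanged(self, small_catalogue,
                                                     normalized, design):
        rt1 = hd.build_ratio_table(normalized.rpkm, design.samples(),
                                   small_catalogue.pairs)
        rt2 = hd.build_ratio_table(normalized.rpkm * 3.7, design.samples(),
                                   small_catalogue.pairs)
        pd.testing.assert_series_equal(rt1.table.ratio, rt2.table.ratio)
        pd.testing.assert_series_equal(rt1.table.balance, rt2.table.balance)


class TestBalanceClassification:
    @pytest.mark.parametrize("ratio,expected", [
        (0.39, "unbalanced_B"), (0.4, "unbalanced_B"), (0.41, "balanced"),
        (0.5, "balanced"), (0.59, "balanced"), (0.6, "unbalanced_A"),
        (0.61, "unbalanced_A"), (np.nan, "undefined"),
    ])
    def test_inclusive_thresholds(self, ratio, expected):
        assert classify_balance(ratio) == expected


class TestBinomial:
    def test_symmetric_counts_give_p_one(self):
        assert adjusted_binomial_pvalue(100, 100, 4) == 1.0

    @pytest.mark.parametrize("k,m", [(7, 3), (60, 40), (2151, 1985)])
    def test_matches_exhaustive_pmf_summation(self, k, m):
        # oracle: sum all outcome probabilities <= that of the observed k
        n = k + m
        pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
        p_exact = pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()
        ours = adjusted_binomial_pvalue(k, m, family_size=1)
        assert ours == pytest.approx(p_exact, rel=1e-3)

    def test_bonferroni_caps_at_one(self):
        assert adjusted_binomial_pvalue(51, 49, 4) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjusted_binomial_pvalue(-1, 5)
        with pytest.raises(ValueError):
            adjusted_binomial_pvalue(1, 5, family_size=0)


class TestSkewness:
    def test_symmetric_vector_zero(self):
        x = np.array([0.2, 0.4, 0.6, 0.8])  # mirror-symmetric around 0.5
        assert hd.skewness(x) == pytest.approx(0.0, abs=1e-12)

    def test_type3_matches_hand_moments(self):
        x = np.array([1.0, 2.0, 10.0])
        m2 = np.mean((x - x.mean()) ** 2)
        m3 = np.mean((x - x.mean()) ** 3)
        expected = m3 / m2 ** 1.5 * ((len(x) - 1) / len(x)) ** 1.5
        assert hd.skewness(x, "type3") == pytest.approx(expected)

    def test_estimator_types_relate_correctly(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        n = len(x)
        g1 = hd.skewness(x, "type1")
        assert hd.skewness(x, "type2") == pytest.approx(
            g1 * np.sqrt(n * (n - 1)) / (n - 2))
        assert hd.skewness(x, "type3") == pytest.approx(
            g1 * ((n - 1) / n) ** 1.5)

    @given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_sign_flips_under_reflection(self, vals):
        x = np.asarray(vals)
        if x.std() == 0:
            return
        assert hd.skewness(1 - x) == pytest.approx(-hd.skewness(x), abs=1e-8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            hd.skewness([1.0, 1.0, 1.0])


class TestGroupSummary:
    def test_all_half_ratios(self):
        s = summarize_group([0.5] * 10, "g")
        assert s.n_Ab == 0 and s.n_aB == 0 and s.n_ties == 10
        assert s.pct_unbalanced == 0.0
        assert s.binom_p_adjusted == 1.0

    def test_counts_and_unbalanced_percentage(self):
        ratios = [0.3, 0.4, 0.45, 0.55, 0.6, 0.61, 0.5, np.nan]
        s = summarize_group(ratios, "g")
        assert s.n_pairs == 7 and s.n_undefined == 1
        assert s.n_Ab == 3 and s.n_aB == 3 and s.n_ties == 1
        assert s.pct_unbalanced == pytest.approx(100 * 4 / 7)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([np.nan, np.nan])

    def test_summarize_table_one_row_per_group(self, small_catalogue,
                                               normalized, design):
        rt = hd.build_ratio_table(normalized.rpkm, design.samples(),
                                  small_catalogue.pairs)
        summaries = summarize_ratio_table(rt.table)
        assert {s.group for s in summaries} == {
            "control_t18", "control_t42", "stress_t18", "stress_t42"}


class TestVarianceDivergence:
    def test_identical_vectors_do_not_reject(self):
        rng = np.random.default_rng(0)
        x = rng.beta(30, 30, 500)
        stat, p = hd.variance_divergence_test(x, x)
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert p > 0.99

    def test_power_on_wide_vs_narrow_beta(self):
        rng = np.random.default_rng(1)
        stress = rng.beta(6, 6, 4000)
        control = rng.beta(30, 30, 4000)
        _, p = hd.variance_divergence_test(stress, control)
        assert p < 1e-10

    def test_null_type_one_error_calibrated(self):
        # 2000 same-distribution replicates: rejection rate ~ alpha
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.beta(20, 20, 150)
            y = rng.beta(20, 20, 150)
            _, p = hd.variance_divergence_test(x, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            hd.variance_divergence_test([0.5], [0.4, 0.6])
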