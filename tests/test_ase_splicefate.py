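"""Allele-specific expression summaries and the transcript-fate model fit."""

import numpy as np
import pandas as pd
import pytest
from _oracles import wilcoxon_enumeration

from splicefate._stats import wilcoxon_rank_sum
from splicefate.ase_splicefate import (
    allelic_fraction_summary,
    compare_expression,
    fit_fate_model,
    fpkm,
    intron_retention_summary,
    microarray_mlr_compare,
)
from splicefate.exceptions import CollinearityError, InvalidArgumentError
from splicefate.synthetic_data import FateModelParams, simulate_ase_counts


def ase_table(carrier_rows, noncarrier_rows):
    """Rows: (exon, intron, alt, ref)."""
    rows = [(1, *r) for r in carrier_rows] + [(0, *r) for r in noncarrier_rows]
    return pd.DataFrame(
        rows, columns=["carrier", "exon_count", "intron_count", "alt_count", "ref_count"]
    ).assign(sample_id=lambda d: [f"S{i}" for i in range(len(d))])


class TestWilcoxon:
    def test_disjoint_small_groups_exact(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([2, 2, 2], [2, 2, 2]) == 1.0

    @pytest.mark.parametrize("x, y", [
        ([1, 2, 3], [4, 5, 6]),
        ([1.5, 2.5], [0.5, 3.5, 4.0]),
        ([1, 1, 2, 3], [2, 4, 4, 5]),        # ties across groups
        ([5, 6, 7, 8, 9], [1, 2, 3]),
        ([0.1, 0.2, 0.2, 0.9], [0.2, 0.3]),  # heavy ties
    ])
    def test_matches_full_enumeration_for_small_groups(self, x, y):
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_enumeration(x, y), abs=1e-9)

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.normal(0.0, 1, 200)
        y = rng.normal(0.5, 1, 200)
        p = wilcoxon_rank_sum(x, y)
        from scipy import stats

        expected = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(expected, rel=1e-9)


class TestCompareExpression:
    def test_printed_medians_give_38_percent_reduction(self):
        # groups constructed to have medians 34.1 (non-carriers) and 21.1 (carriers)
        samples = pd.DataFrame({
            "carrier": [0] * 5 + [1] * 5,
            "expression": [30.0, 34.1, 40.0, 33.0, 36.0, 18.0, 21.1, 25.0, 20.0, 22.0],
        })
        cmp_ = compare_expression(samples)
        assert cmp_.noncarrier_value == pytest.approx(34.1)
        assert cmp_.carrier_value == pytest.approx(21.1)
        assert cmp_.percent_reduction == pytest.approx(100 * (1 - 21.1 / 34.1), abs=1e-9)

    def test_identical_groups_zero_reduction(self):
        samples = pd.DataFrame({"carrier": [0, 0, 1, 1],
                                "expression": [5.0, 7.0, 5.0, 7.0]})
        cmp_ = compare_expression(samples)
        assert cmp_.percent_reduction == pytest.approx(0.0)
        assert cmp_.wilcoxon_p == 1.0

    def test_zero_noncarrier_median_flagged(self):
        samples = pd.DataFrame({"carrier": [0, 0, 1, 1],
                                "expression": [0.0, 0.0, 1.0, 2.0]})
        assert compare_expression(samples).percent_reduction is None

    def test_empty_group_rejected(self):
        samples = pd.DataFrame({"carrier": [1, 1], "expression": [1.0, 2.0]})
        with pytest.raises(InvalidArgumentError):
            compare_expression(samples)


class TestAllelicFraction:
    def test_zero_alt_gives_zero_fraction(self):
        tab = ase_table([(100, 0, 0, 50)], [(100, 0, 25, 25)])
        cmp_ = allelic_fraction_summary(tab, min_depth=10)
        assert cmp_.carrier_value == 0.0
        assert cmp_.noncarrier_value == pytest.approx(0.5)

    def test_simulated_nmd_quarter_survival_gives_one_fifth(self):
        params = FateModelParams(s=0.25, rho=0.5, b=0.5, lambda_expr=2000.0)
        tab = simulate_ase_counts([1] * 60 + [0] * 60, params, seed=1)
        cmp_ = allelic_fraction_summary(tab, min_depth=10)
        assert cmp_.carrier_value == pytest.approx(0.25 / 1.25, abs=0.01)

    def test_reference_bias_shifts_noncarrier_mean(self):
        params = FateModelParams(s=0.25, rho=0.5, b=0.48, lambda_expr=5000.0)
        tab = simulate_ase_counts([0] * 80, params, seed=2)
        tab.loc[0, "carrier"] = 1  # need one carrier for the grouping
        cmp_ = allelic_fraction_summary(tab, min_depth=10)
        assert cmp_.noncarrier_value == pytest.approx(0.48, abs=0.01)

    def test_depth_filter_counts_exclusions(self):
        tab = ase_table([(100, 0, 3, 4), (100, 0, 200, 800)], [(100, 0, 50, 50)])
        cmp_ = allelic_fraction_summary(tab, min_depth=10)
        assert cmp_.n_excluded == 1
        with pytest.raises(InvalidArgumentError):
            allelic_fraction_summary(tab, min_depth=10_000)

    def test_invariant_to_binomial_thinning(self, rng):
        """Expected fractions unchanged under 50% down-sampling of reads."""
        params = FateModelParams(s=0.25, rho=0.0, b=0.5, lambda_expr=8000.0)
        tab = simulate_ase_counts([1] * 100 + [0] * 100, params, seed=3)
        full = allelic_fraction_summary(tab, min_depth=10)
        thinned = tab.copy()
        thinned["alt_count"] = rng.binomial(tab["alt_count"], 0.5)
        thinned["ref_count"] = rng.binomial(tab["ref_count"], 0.5)
        half = allelic_fraction_summary(thinned, min_depth=10)
        assert half.carrier_value == pytest.approx(full.carrier_value, abs=0.01)
        assert half.noncarrier_value == pytest.approx(full.noncarrier_value, abs=0.01)


class TestIntronRetention:
    def test_zero_intron_reads_zero_ratio(self):
        tab = ase_table([(100, 0, 10, 10)], [(100, 0, 10, 10)])
        cmp_ = intron_retention_summary(tab)
        assert cmp_.carrier_value == 0.0

    def test_simulated_retention_matches_fate_expectation(self):
        """s=0.25, rho=0.5, baseline 0.0067: carrier ratio ~ 0.10 + baseline."""
        params = FateModelParams(s=0.25, rho=0.5, b=0.5, lambda_expr=20_000.0,
                                 baseline_intron=0.0067)
        tab = simulate_ase_counts([1] * 80 + [0] * 80, params, seed=4)
        cmp_ = intron_retention_summary(tab)
        expected = 0.5 * 0.25 / 1.25 + 0.0067
        assert cmp_.carrier_value == pytest.approx(expected, abs=0.005)
        assert cmp_.noncarrier_value == pytest.approx(0.0067, abs=0.002)

    def test_zero_exon_sample_excluded(self):
        tab = ase_table([(100, 5, 10, 10), (0, 5, 10, 10)], [(100, 1, 10, 10)])
        cmp_ = intron_retention_summary(tab)
        assert cmp_.n_excluded == 1
        assert cmp_.n_carrier == 1

    def test_length_normalization(self):
        tab = ase_table([(100, 10, 10, 10)], [(100, 1, 10, 10)])
        raw = intron_retention_summary(tab)
        norm = intron_retention_summary(tab, intron_length=500.0, exon_length=1000.0)
        assert norm.carrier_value == pytest.approx(2 * raw.carrier_value)


class TestFateModel:
    def test_complete_nmd_limit(self):
        fit = fit_fate_model(carrier_allelic_fraction=0.0)
        assert fit.s_hat == 0.0
        assert fit.predicted_het_ratio == pytest.approx(0.5)

    def test_one_fifth_allelic_fraction_implies_quarter_survival(self):
        fit = fit_fate_model(carrier_allelic_fraction=0.20)
        assert fit.s_hat == pytest.approx(0.25)
        assert fit.predicted_het_ratio == pytest.approx(0.625)  # 37.5% reduction

    def test_round_trip_parameter_recovery(self):
        """Simulate s=0.4, rho=0.3 deeply; recover s within 0.03, rho within 0.05."""
        params = FateModelParams(s=0.4, rho=0.3, b=0.5, lambda_expr=20_000.0,
                                 baseline_intron=0.0)
        tab = simulate_ase_counts([1] * 100 + [0] * 100, params, seed=5)
        af = allelic_fraction_summary(tab, min_depth=10)
        ir = intron_retention_summary(tab)
        ratio = (tab[tab.carrier == 1].exon_count.mean()
                 / tab[tab.carrier == 0].exon_count.mean())
        fit = fit_fate_model(het_ratio=ratio,
                             carrier_allelic_fraction=af.carrier_value,
                             carrier_intron_share=ir.carrier_value)
        assert fit.s_hat == pytest.approx(0.4, abs=0.03)
        assert fit.rho_hat == pytest.approx(0.3, abs=0.05)
        assert not fit.flagged

    def test_reference_bias_generalization(self):
        """With bias b, a = b*s/(b*s + 1-b); the fit inverts it."""
        b, s = 0.48, 0.25
        a = b * s / (b * s + (1 - b))
        fit = fit_fate_model(carrier_allelic_fraction=a, b=b)
        assert fit.s_hat == pytest.approx(s, abs=1e-9)

    def test_inconsistent_inputs_flagged_not_raised(self):
        fit = fit_fate_model(het_ratio=0.95, carrier_allelic_fraction=0.1)
        assert fit.flagged and "disagree" in fit.note

    def test_internal_consistency_of_printed_observables(self):
        """Published medians 34.1/21.1 imply a mutant-chromosome share near 0.20."""
        r = 21.1 / 34.1
        fit = fit_fate_model(het_ratio=r)
        implied_share = fit.s_hat / (1 + fit.s_hat)
        assert implied_share == pytest.approx(0.20, abs=0.02)

    def test_input_validation(self):
        with pytest.raises(InvalidArgumentError):
            fit_fate_model()
        with pytest.raises(InvalidArgumentError):
            fit_fate_model(carrier_allelic_fraction=1.0)


class TestMicroarrayAndFpkm:
    def test_null_mlr_gives_unit_level(self):
        out = microarray_mlr_compare(np.zeros(30), np.repeat([0.0, 1.0, 2.0], 10))
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(1.0) for v in out["per_genotype_level"].values())

    def test_mean_log_ratio_half_gives_level(self):
        mlr = np.array([0.5] * 10 + [0.0] * 10)
        dose = np.array([0.0] * 10 + [1.0] * 10)
        out = microarray_mlr_compare(mlr, dose)
        assert out["per_genotype_level"][0] == pytest.approx(10**0.5, abs=1e-9)

    def test_slope_recovery(self, rng):
        dose = rng.binomial(2, 0.4, 2000).astype(float)
        mlr = -0.1 * dose + rng.normal(0, 0.05, 2000)
        out = microarray_mlr_compare(mlr, dose)
        assert out["slope"] == pytest.approx(-0.1, abs=3 * out["se"])
        assert out["p"] < 1e-10

    def test_collinear_design_rejected(self):
        with pytest.raises(CollinearityError):
            microarray_mlr_compare(np.ones(10), np.ones(10))

    def test_fpkm_definition_and_scaling(self):
        assert fpkm(0, 1000, 1e6) == 0.0
        assert fpkm(1000, 1000, 1e6) == pytest.approx(1000.0)
        assert fpkm(1000, 1000, 2e6) == pytest.approx(fpkm(1000, 1000, 1e6) / 2)
        with pytest.raises(InvalidArgumentError):
            fpkm(10, 0, 1e6)
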