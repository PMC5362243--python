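"""Mixed-model and logistic association tests, genomic control, thresholds."""

import numpy as np
import pandas as pd
import pytest
from _oracles import gls_oracle

from splicefate.association import (
    KinshipWhitener,
    apply_genomic_control,
    bonferroni_threshold,
    class_threshold,
    fit_lmm,
    fit_logistic,
    ld_score_regression_intercept,
    load_class_thresholds,
)
from splicefate.exceptions import (
    ConfigurationError,
    InvalidArgumentError,
    MonomorphicVariantError,
    SeparationError,
)
from splicefate.synthetic_data import (
    KinshipMatrix,
    VariantPanel,
    VariantRecord,
    kinship_from_pedigree,
    simulate_genotypes,
    simulate_pedigree,
    simulate_quantitative_phenotype,
)


def identity_phi(n):
    return KinshipMatrix([f"i{k}" for k in range(n)], 0.5 * np.eye(n))


class TestFitLmm:
    def test_collapses_to_ols_when_relationship_identity(self, rng):
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.2 * g + rng.standard_normal(n)
        res = fit_lmm(y, g, phi=identity_phi(n))
        x = np.column_stack([np.ones(n), g])
        coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        assert res.beta == pytest.approx(coef[1], abs=1e-8)
        resid = y - x @ coef
        sigma2_ml = (resid @ resid) / n
        se_ml = np.sqrt(sigma2_ml * np.linalg.inv(x.T @ x)[1, 1])
        assert res.se == pytest.approx(se_ml, abs=1e-8)
        res_no_phi = fit_lmm(y, g)
        assert res_no_phi.beta == pytest.approx(res.beta, abs=1e-10)
        assert res_no_phi.chi2_lrt == pytest.approx(res.chi2_lrt, abs=1e-8)

    def test_toy_sib_pair_matches_explicit_gls(self, rng):
        """n=6 with one sib pair: beta matches brute-force GLS inversion."""
        ids = [f"i{k}" for k in range(6)]
        phi = 0.5 * np.eye(6)
        phi[4, 5] = phi[5, 4] = 0.25  # full sibs
        k = KinshipMatrix(ids, phi)
        g = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 0.0])
        y = np.array([0.3, -0.1, 1.2, 0.4, -0.5, 0.2])
        res = fit_lmm(y, g, phi=k, variance_ratio=1.0)
        x = np.column_stack([np.ones(6), g])
        beta, cov_unit = gls_oracle(y, x, 2.0 * phi)
        assert res.beta == pytest.approx(beta[1], abs=1e-8)
        v_inv = np.linalg.inv(2.0 * phi)
        r = y - x @ beta
        sigma2 = float(r @ v_inv @ r) / 6
        assert res.se == pytest.approx(np.sqrt(sigma2 * cov_unit[1, 1]), abs=1e-8)

    def test_covariates_supported_inside_fit(self, rng):
        n = 1000
        g = rng.binomial(2, 0.4, n).astype(float)
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.15 * g + 0.8 * sex + rng.standard_normal(n)
        res_adj = fit_lmm(y, g, covariates=pd.DataFrame({"sex": sex}))
        se_naive = 1.0 / np.sqrt(n * g.var())
        assert abs(res_adj.beta - 0.15) < 3.5 * se_naive

    def test_lrt_matches_squared_wald_at_large_n(self, rng):
        n = 10_000
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.05 * g + rng.standard_normal(n)
        res = fit_lmm(y, g)
        wald2 = (res.beta / res.se) ** 2
        assert res.chi2_lrt == pytest.approx(wald2, rel=0.05)

    def test_effect_recovery_over_replicates(self):
        """Mean of beta-hat over 50 kinship-aware replicate fits within 3 SEM."""
        from splicefate.synthetic_data import simulate_family_cohort

        ped = simulate_family_cohort(1500, seed=30)
        phi = kinship_from_pedigree(ped)
        whitener = KinshipWhitener(phi)
        panel = VariantPanel([VariantRecord("v", "chr9", 6_000_000, "G", "C", 0.25)])
        betas = []
        for r in range(50):
            haps = simulate_genotypes(ped, panel, seed=100 + r)
            ph = simulate_quantitative_phenotype(
                haps, {"v": -0.1}, phi=phi, h2_family=0.3, seed=500 + r
            )
            betas.append(fit_lmm(ph["phenotype"], haps.dosage_of("v"), phi=whitener).beta)
        betas = np.array(betas)
        sem = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - (-0.1)) < 3 * sem

    def test_monomorphic_and_misaligned_rejected(self, rng):
        y = rng.standard_normal(10)
        with pytest.raises(MonomorphicVariantError):
            fit_lmm(y, np.zeros(10))
        from splicefate.exceptions import AlignmentError
        with pytest.raises(AlignmentError):
            fit_lmm(y, np.ones(5))

    def test_non_positive_definite_kinship_rejected(self):
        ids = ["a", "b"]
        phi = np.array([[0.5, 0.6], [0.6, 0.5]])  # off-diagonal > diagonal
        with pytest.raises(InvalidArgumentError):
            KinshipWhitener(KinshipMatrix(ids, phi))


class TestFitLogistic:
    def test_null_variant_odds_ratio_near_one(self, rng):
        n = 8000
        g = rng.binomial(2, 0.3, n).astype(float)
        status = rng.binomial(1, 0.3, n)
        res = fit_logistic(status, g)
        assert res.or_ == pytest.approx(1.0, abs=3.5 * res.se)
        assert res.or_ == pytest.approx(np.exp(res.beta))

    def test_matches_woolf_cross_product_ratio(self, rng):
        n = 5000
        g = rng.binomial(1, 0.2, n).astype(float)  # binary exposure
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * g)))
        status = rng.binomial(1, p)
        res = fit_logistic(status, g)
        a = np.sum((g == 1) & (status == 1))
        b = np.sum((g == 1) & (status == 0))
        c = np.sum((g == 0) & (status == 1))
        d = np.sum((g == 0) & (status == 0))
        assert res.or_ == pytest.approx(a * d / (b * c), abs=1e-6)

    def test_complete_separation_raises(self):
        g = np.array([0.0] * 10 + [1.0] * 10)
        status = np.array([0] * 10 + [1] * 10)
        with pytest.raises(SeparationError):
            fit_logistic(status, g)

    def test_single_class_rejected(self, rng):
        g = rng.binomial(2, 0.3, 20).astype(float)
        with pytest.raises(InvalidArgumentError):
            fit_logistic(np.ones(20), g)


class TestGenomicControl:
    def test_ldsc_flat_chi2_gives_unit_intercept(self):
        scores = np.linspace(1, 50, 500)
        fit = ld_score_regression_intercept(np.ones(500), scores)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_ldsc_recovers_simulated_intercept(self, rng):
        scores = rng.uniform(1, 100, 5000)
        chi2 = 1.2 + 0.01 * scores + rng.normal(0, 0.3, 5000)
        fit = ld_score_regression_intercept(chi2, scores)
        assert fit.intercept == pytest.approx(1.2, abs=3 * fit.intercept_se)

    def test_ldsc_input_validation(self, rng):
        with pytest.raises(InvalidArgumentError):
            ld_score_regression_intercept(np.ones(50), np.arange(50.0))
        with pytest.raises(InvalidArgumentError):
            ld_score_regression_intercept(np.ones(200), np.full(200, 5.0))

    def test_correction_arithmetic(self):
        from splicefate.association import AssocResult

        res = [AssocResult("v", 0.1, 0.05, 10.0, 0.0016, 100)]
        out = apply_genomic_control(res, 1.2844)
        assert out[0].chi2_corrected == pytest.approx(10.0 / 1.2844, abs=1e-4)
        assert out[0].chi2_corrected == pytest.approx(7.7857, abs=1e-3)
        assert out[0].p_corrected > out[0].p_raw

    def test_lambda_one_or_below_leaves_p_unchanged(self):
        from splicefate.association import AssocResult

        res = [AssocResult("v", 0.1, 0.05, 3.84, 0.05004, 100)]
        for lam in (1.0, 0.8):
            out = apply_genomic_control(res, lam)
            assert out[0].p_corrected == res[0].p_raw

    def test_borderline_significance_lost_at_lambda_two(self):
        from scipy import stats as ss

        from splicefate.association import AssocResult

        p_raw = float(ss.chi2.sf(3.84, 1))
        res = [AssocResult("v", 0.1, 0.05, 3.84, p_raw, 100)]
        out = apply_genomic_control(res, 2.0)
        assert p_raw == pytest.approx(0.05, abs=0.001)
        assert out[0].p_corrected > 0.05

    def test_monotone_in_lambda(self):
        from splicefate.association import AssocResult

        res = [AssocResult("v", 0.1, 0.05, 8.0, 0.0047, 100)]
        ps = [apply_genomic_control(res, lam)[0].p_corrected
              for lam in (1.0, 1.1, 1.5, 2.0, 3.0)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))

    def test_invalid_lambda(self):
        with pytest.raises(InvalidArgumentError):
            apply_genomic_control([], 0.0)


class TestClassThresholds:
    def test_impact_monotonicity(self):
        table = load_class_thresholds()
        assert table["loss_of_function"] >= table["missense"]
        assert table["missense"] >= table["synonymous"]
        assert table["synonymous"] >= table["intergenic"]
        assert class_threshold("loss_of_function") >= class_threshold("intergenic")

    def test_unknown_class_lists_known(self):
        with pytest.raises(ConfigurationError, match="intergenic"):
            class_threshold("promoter")

    def test_config_override(self, tmp_path):
        cfg = tmp_path / "thr.yaml"
        cfg.write_text(
            "class_thresholds:\n"
            + "\n".join(f"  {c}: 1.0e-5" for c in
                        ("loss_of_function", "missense", "splice_region", "synonymous",
                         "upstream", "intronic", "intergenic"))
        )
        table = load_class_thresholds(cfg)
        assert class_threshold("intronic", table) == pytest.approx(1e-5)

    def test_region_bonferroni(self):
        thr = bonferroni_threshold(17_935)
        assert thr == pytest.approx(2.79e-6, abs=0.01e-6)
        with pytest.raises(InvalidArgumentError):
            bonferroni_threshold(0)
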