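"""End-to-end study drivers at the published conditions.

These functions wire the simulators to the estimators at the sample sizes,
allele frequency and effect sizes of the source study (Iceland eosinophil
effect -0.21 SD per allele at AF 0.65%; NMD survival 0.25 on the mutant
chromosome) so the pipeline's recovery of those quantities can be measured
from scratch.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .ase_splicefate import (
    allelic_fraction_summary,
    compare_expression,
    fit_fate_model,
    intron_retention_summary,
)
from .association import KinshipWhitener, fit_lmm
from .io import read_cohort_estimates
from .meta_analysis import CohortEstimate, cohorts_from_frame
from .synthetic_data import (
    FateModelParams,
    VariantPanel,
    VariantRecord,
    kinship_from_pedigree,
    simulate_ase_counts,
    simulate_family_cohort,
    simulate_genotypes,
    simulate_quantitative_phenotype,
)

# published splice-acceptor variant parameters (Iceland discovery cohort)
SPLICE_VARIANT_AF = 0.0065
ICELAND_EOS_BETA = -0.21
NMD_SURVIVAL = 0.25
INTRON_RETENTION = 0.5


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n child seeds (< 2^31) from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def published_cohorts(trait: str) -> list[CohortEstimate]:
    """Published per-cohort estimates ('asthma' ORs or 'eosinophils' betas)."""
    fname = {"asthma": "asthma_cohorts.tsv", "eosinophils": "eosinophil_cohorts.tsv"}[trait]
    ref = resources.files("splicefate").joinpath(f"data/{fname}")
    return cohorts_from_frame(read_cohort_estimates(str(ref)))


def ase_fate_study(
    n_carriers: int = 50,
    n_noncarriers: int = 50,
    s: float = NMD_SURVIVAL,
    rho: float = INTRON_RETENTION,
    reads_per_sample: float = 2000.0,
    seed: int = 0,
) -> dict:
    """Simulate ASE counts under the fate model and recover its observables.

    ``reads_per_sample`` is the target mean informative (ALT+REF) read depth
    in carriers; the per-chromosome emission rate is scaled accordingly.
    Returns the carrier allelic fraction, het/non expression ratio, intron
    share and the inverted fate-model fit.
    """
    lam = reads_per_sample / ((1.0 + s) / 2.0)
    params = FateModelParams(s=s, rho=rho, b=0.5, lambda_expr=lam)
    flags = [1] * n_carriers + [0] * n_noncarriers
    table = simulate_ase_counts(flags, params, seed=seed)

    af = allelic_fraction_summary(table, min_depth=10)
    expr = compare_expression(table)
    intron = intron_retention_summary(table)
    car = table[table.carrier == 1]
    non = table[table.carrier == 0]
    het_ratio = float(car.exon_count.mean() / non.exon_count.mean())
    fractions = car.alt_count / (car.alt_count + car.ref_count)
    fit = fit_fate_model(
        het_ratio=het_ratio,
        carrier_allelic_fraction=af.carrier_value,
        carrier_intron_share=intron.carrier_value - intron.noncarrier_value,
    )
    return {
        "table": table,
        "carrier_alt_fraction": af.carrier_value,
        "carrier_alt_fraction_se": float(fractions.std(ddof=1) / np.sqrt(len(fractions))),
        "noncarrier_alt_fraction": af.noncarrier_value,
        "het_expression_ratio": het_ratio,
        "expression_percent_reduction": expr.percent_reduction,
        "carrier_intron_share": intron.carrier_value,
        "fate_fit": fit,
    }


def lmm_recovery_study(
    n_replicates: int = 50,
    n_individuals: int = 20_000,
    beta: float = ICELAND_EOS_BETA,
    allele_frequency: float = SPLICE_VARIANT_AF,
    h2_family: float = 0.2,
    max_family_size: int = 20,
    seed: int = 0,
) -> dict:
    """Replicate kinship-aware mixed-model fits at the published effect size.

    Each replicate simulates a fresh family cohort, genotypes one variant at
    the published allele frequency, generates the phenotype with the family
    variance component, and fits the mixed model.  Returns the per-replicate
    estimates and their mean/SEM.
    """
    seeds = _spawn_seeds(seed, 3 * n_replicates).reshape(n_replicates, 3)
    panel = VariantPanel(
        [VariantRecord("splice_variant", "chr9", 6_209_697, "G", "C",
                       allele_frequency, "loss_of_function")]
    )
    betas = np.empty(n_replicates)
    for r in range(n_replicates):
        s_ped, s_gen, s_phe = (int(x) for x in seeds[r])
        ped = simulate_family_cohort(n_individuals, max_family_size=max_family_size,
                                     seed=s_ped)
        phi = kinship_from_pedigree(ped)
        haps = simulate_genotypes(ped, panel, seed=s_gen)
        pheno = simulate_quantitative_phenotype(
            haps, {"splice_variant": beta}, phi=phi, h2_family=h2_family, seed=s_phe
        )
        res = fit_lmm(pheno["phenotype"], haps.dosage_of("splice_variant"),
                      phi=phi, variant_id="splice_variant")
        betas[r] = res.beta
    return {
        "betas": betas,
        "mean_beta": float(betas.mean()),
        "sem": float(betas.std(ddof=1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
        "n_individuals": n_individuals,
    }


def simulated_locus_cohort(n_individuals: int = 60_000, seed: int = 0):
    """A family cohort over a synthetic 800 kb locus with two true signals.

    The locus mirrors the architecture the fine-mapping stage must resolve:
    a rare loss-of-function variant (AF 0.65%, effect -0.21 SD) independent
    of a common upstream variant (AF 24.5%, effect +0.051 SD) that drags two
    LD proxies (r^2 ~ 0.8) along, plus a null LD block.  Returns
    (CohortData, truth dict).
    """
    from .conditional_finemap import CohortData
    from .synthetic_data import LdBlock

    panel = VariantPanel(
        [
            VariantRecord("common_upstream", "chr9", 6_190_000, "T", "C", 0.245, "upstream"),
            VariantRecord("proxy_1", "chr9", 6_195_000, "G", "A", 0.245, "intergenic"),
            VariantRecord("proxy_2", "chr9", 6_201_000, "C", "T", 0.245, "intronic"),
            VariantRecord("splice_variant", "chr9", 6_209_697, "G", "C",
                          SPLICE_VARIANT_AF, "loss_of_function"),
            VariantRecord("null_a", "chr9", 6_310_000, "A", "G", 0.40, "intronic"),
            VariantRecord("null_b", "chr9", 6_315_000, "G", "T", 0.40, "intronic"),
            VariantRecord("null_far", "chr9", 6_480_000, "C", "A", 0.30, "intergenic"),
        ],
        [LdBlock((0, 1, 2), 0.8), LdBlock((4, 5), 0.5)],
    )
    truth = {"splice_variant": ICELAND_EOS_BETA, "common_upstream": 0.051}
    seeds = _spawn_seeds(seed, 3)
    ped = simulate_family_cohort(n_individuals, seed=int(seeds[0]))
    phi = kinship_from_pedigree(ped)
    haps = simulate_genotypes(ped, panel, seed=int(seeds[1]))
    pheno = simulate_quantitative_phenotype(
        haps, truth, phi=phi, h2_family=0.2, seed=int(seeds[2])
    )
    cohort = CohortData.from_haplotypes(
        haps, phenotype=pheno["phenotype"].to_numpy(), phi=phi
    )
    return cohort, truth


def null_calibration_study(
    n_fits: int = 2000,
    n_individuals: int = 500,
    h2_family: float = 0.3,
    allele_frequency: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the mixed-model LRT on family-structured null data.

    The pedigree and genotypes are fixed (one draw) and the null phenotype
    is redrawn per fit — the conditional-on-genotypes framing of test
    calibration.
    """
    base = _spawn_seeds(seed, 2 + n_fits)
    ped = simulate_family_cohort(n_individuals, seed=int(base[0]))
    phi = kinship_from_pedigree(ped)
    whitener = KinshipWhitener(phi)
    panel = VariantPanel(
        [VariantRecord("null_variant", "chr9", 6_000_000, "G", "C", allele_frequency)]
    )
    haps = simulate_genotypes(ped, panel, seed=int(base[1]))
    g = haps.dosage_of("null_variant")
    rejections = 0
    for i in range(n_fits):
        pheno = simulate_quantitative_phenotype(
            haps, {}, phi=phi, h2_family=h2_family, seed=int(base[2 + i])
        )
        res = fit_lmm(pheno["phenotype"], g, phi=whitener)
        rejections += res.p_raw < alpha
    return {
        "rejection_rate": rejections / n_fits,
        "n_fits": n_fits,
        "n_individuals": len(ped),
    }
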