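"""Expression consequences of a splice-acceptor loss-of-function variant.

Three observables distinguish the fate of transcripts from the mutated
chromosome in heterozygous carriers:

* total expression relative to non-carriers (reduced when mutant transcripts
  are degraded by nonsense-mediated decay),
* the allelic fraction at a transcribed tagging SNP phased with the mutation
  (the share of reads from the mutant chromosome),
* the intron/exon coverage ratio at the affected intron (elevated when
  surviving mutant transcripts retain the intron).

Under the transcript-fate model with NMD survival ``s``, retention fraction
``rho`` and no mapping bias, the expected observables are
het/non expression ratio (1+s)/2, carrier allelic fraction s/(1+s) and
carrier intron-retaining share rho*s/(1+s); ``fit_fate_model`` inverts these
identities to recover (s, rho) from the summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._stats import wilcoxon_rank_sum
from .exceptions import CollinearityError, InvalidArgumentError

__all__ = [
    "GroupComparison",
    "FateFit",
    "compare_expression",
    "allelic_fraction_summary",
    "intron_retention_summary",
    "fit_fate_model",
    "microarray_mlr_compare",
    "fpkm",
]


@dataclass
class GroupComparison:
    """Carrier vs non-carrier summary of one observable."""

    statistic: str  # "median" or "mean"
    noncarrier_value: float
    carrier_value: float
    percent_reduction: float | None
    wilcoxon_p: float
    n_noncarrier: int
    n_carrier: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _split(samples: pd.DataFrame, column: str) -> tuple[np.ndarray, np.ndarray]:
    if "carrier" not in samples.columns:
        raise InvalidArgumentError("samples need a 'carrier' column")
    car = samples.loc[samples["carrier"].astype(bool), column].to_numpy(dtype=float)
    non = samples.loc[~samples["carrier"].astype(bool), column].to_numpy(dtype=float)
    if car.size == 0 or non.size == 0:
        raise InvalidArgumentError("both carrier and non-carrier groups must be non-empty")
    return non, car


def _percent_reduction(non: float, car: float) -> float | None:
    if non <= 0:
        return None  # undefined; flagged by None
    return float(100.0 * (1.0 - car / non))


def compare_expression(samples: pd.DataFrame, column: str = "expression") -> GroupComparison:
    """Median expression by carrier status with a two-sided Wilcoxon rank-sum p.

    ``column`` defaults to an FPKM-like 'expression' column; falls back to
    'exon_count' when absent (raw-count cohorts from the simulator).
    """
    if column not in samples.columns and "exon_count" in samples.columns:
        column = "exon_count"
    non, car = _split(samples, column)
    med_n, med_c = float(np.median(non)), float(np.median(car))
    return GroupComparison(
        "median", med_n, med_c, _percent_reduction(med_n, med_c),
        wilcoxon_rank_sum(car, non), non.size, car.size,
    )


def allelic_fraction_summary(samples: pd.DataFrame, min_depth: int = 10) -> GroupComparison:
    """Mean per-sample ALT-read fraction alt/(alt+ref) by carrier status.

    Samples with fewer than ``min_depth`` reads over the tagging SNP are
    excluded (and counted); the comparison is means, as the fractions are
    already bounded and roughly symmetric at depth.
    """
    depth = samples["alt_count"] + samples["ref_count"]
    kept = samples.loc[depth >= min_depth].copy()
    n_excluded = len(samples) - len(kept)
    if kept.empty:
        raise InvalidArgumentError(f"no samples with depth >= {min_depth}")
    kept["af"] = kept["alt_count"] / (kept["alt_count"] + kept["ref_count"])
    non, car = _split(kept, "af")
    mean_n, mean_c = float(non.mean()), float(car.mean())
    return GroupComparison(
        "mean", mean_n, mean_c, _percent_reduction(mean_n, mean_c),
        wilcoxon_rank_sum(car, non), non.size, car.size, n_excluded,
    )


def intron_retention_summary(
    samples: pd.DataFrame,
    intron_length: float | None = None,
    exon_length: float | None = None,
) -> GroupComparison:
    """Mean intron/exon coverage ratio by carrier status.

    Raw read-count ratios by default; per-base normalization applied when
    interval lengths (e.g. from a gene model) are supplied.  Samples with
    zero exon coverage are excluded and counted.
    """
    kept = samples.loc[samples["exon_count"] > 0].copy()
    n_excluded = len(samples) - len(kept)
    if kept.empty:
        raise InvalidArgumentError("no samples with exon coverage")
    ratio = kept["intron_count"] / kept["exon_count"]
    if intron_length is not None and exon_length is not None:
        if intron_length <= 0 or exon_length <= 0:
            raise InvalidArgumentError("interval lengths must be positive")
        ratio = ratio * (exon_length / intron_length)
    kept["ratio"] = ratio
    non, car = _split(kept, "ratio")
    mean_n, mean_c = float(non.mean()), float(car.mean())
    return GroupComparison(
        "mean", mean_n, mean_c, _percent_reduction(mean_n, mean_c),
        wilcoxon_rank_sum(car, non), non.size, car.size, n_excluded,
    )


@dataclass
class FateFit:
    """Transcript-fate parameters inferred from the group summaries."""

    s_hat: float
    rho_hat: float | None
    predicted_het_ratio: float
    consistency_residual: float | None
    flagged: bool = False
    note: str = ""


def fit_fate_model(
    het_ratio: float | None = None,
    carrier_allelic_fraction: float | None = None,
    carrier_intron_share: float | None = None,
    b: float = 0.5,
    tolerance: float = 0.1,
) -> FateFit:
    """Invert the fate-model identities to estimate NMD survival and retention.

    Preference order: the allelic fraction a gives s = a(1-b) / (b(1-a)),
    which reduces to a/(1-a) when b = 0.5; the expression ratio is used as a
    fallback (s = 2r - 1) when no allelic fraction is supplied.  rho follows from the
    carrier intron-retaining share via rho = share*(1+s)/s.  When both
    inputs are present the predicted and observed expression ratios are
    compared; a discrepancy beyond ``tolerance`` flags the fit rather than
    raising.
    """
    if carrier_allelic_fraction is None and het_ratio is None:
        raise InvalidArgumentError("supply at least one of het_ratio or allelic fraction")
    if not 0.0 < b < 1.0:
        raise InvalidArgumentError("b must be in (0,1)")
    if carrier_allelic_fraction is not None:
        a = carrier_allelic_fraction
        if not 0.0 <= a < 1.0:
            raise InvalidArgumentError("allelic fraction must be in [0,1)")
        # a = b*s / (b*s + (1-b))  =>  s = a*(1-b) / (b*(1-a))
        s = a * (1.0 - b) / (b * (1.0 - a))
    else:
        if not 0.0 < het_ratio <= 1.0:
            raise InvalidArgumentError("het/non expression ratio must be in (0,1]")
        s = 2.0 * het_ratio - 1.0
    s = float(np.clip(s, 0.0, 1.0))
    predicted = (1.0 + s) / 2.0

    rho = None
    if carrier_intron_share is not None:
        if not 0.0 <= carrier_intron_share < 1.0:
            raise InvalidArgumentError("intron share must be in [0,1)")
        if s > 0:
            rho = float(np.clip(carrier_intron_share * (1.0 + s) / s, 0.0, 1.0))
        elif carrier_intron_share == 0:
            rho = 0.0  # nothing survives; retention unidentifiable, set by convention

    residual = None
    flagged = False
    note = ""
    if het_ratio is not None and carrier_allelic_fraction is not None:
        residual = float(abs(het_ratio - predicted))
        if residual > tolerance:
            flagged = True
            note = (
                f"observed het/non ratio {het_ratio:.3f} vs predicted "
                f"{predicted:.3f} disagree beyond tolerance {tolerance}"
            )
    return FateFit(s, rho, float(predicted), residual, flagged, note)


def microarray_mlr_compare(mlr, genotype_dosage, covariates=None) -> dict:
    """Regress mean log10 expression ratios (MLR) on allele count.

    Returns the slope/SE/p of the dosage term and the per-genotype-class
    expression level 10^(mean MLR).
    """
    mlr = np.asarray(mlr, dtype=float)
    dose = np.asarray(genotype_dosage, dtype=float)
    if mlr.size != dose.size:
        raise InvalidArgumentError("MLR and dosage not aligned")
    cols = [np.ones(mlr.size), dose]
    if covariates is not None:
        c = covariates.to_numpy(dtype=float) if hasattr(covariates, "to_numpy") else np.asarray(
            covariates, dtype=float
        )
        if c.ndim == 1:
            c = c[:, None]
        cols.append(c)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearityError("rank-deficient MLR design")
    fit = sm.OLS(mlr, x).fit()
    levels = {}
    for cls in sorted(np.unique(np.round(dose).astype(int))):
        members = mlr[np.round(dose).astype(int) == cls]
        levels[int(cls)] = float(10.0 ** members.mean())
    return {
        "slope": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "p": float(fit.pvalues[1]),
        "per_genotype_level": levels,
        "n": int(mlr.size),
    }


def fpkm(counts: float, gene_length: float, total_mapped: float) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if gene_length <= 0 or total_mapped <= 0:
        raise InvalidArgumentError("gene_length and total_mapped must be positive")
    if counts < 0:
        raise InvalidArgumentError("counts must be non-negative")
    return float(counts * 1e9 / (gene_length * total_mapped))
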