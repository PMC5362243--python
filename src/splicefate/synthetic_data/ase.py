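"""Allele-specific RNA read-count simulation under a transcript-fate model.

A heterozygous carrier of the splice-acceptor mutation has one wild-type and
one mutant chromosome.  The wild-type chromosome emits exon reads at rate
``lambda_expr``; the mutant chromosome's transcripts are degraded by
nonsense-mediated decay so that only a fraction ``s`` survive, and of those
a fraction ``rho`` retain the last intron and therefore also produce intron
coverage.  At a transcribed heterozygous tagging SNP phased with the
mutation (ALT on the mutant chromosome), reads report their chromosome of
origin, with reference-mapping bias ``b`` (the ALT-read fraction expected in
a non-carrier heterozygote, 0.5 when unbiased).

Expected observables implied by the model (b = 0.5):

* carrier / non-carrier total expression ratio  r = (1 + s) / 2
* carrier ALT-read fraction                     a = s / (1 + s)
* carrier intron-retaining transcript share     rho * s / (1 + s)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..exceptions import InvalidArgumentError

__all__ = ["FateModelParams", "simulate_ase_counts"]


@dataclass(frozen=True)
class FateModelParams:
    """Generative parameters of the transcript-fate model.

    s: NMD survival fraction of mutant-chromosome transcripts, in [0,1].
    rho: fraction of surviving mutant transcripts retaining the last intron.
    b: ALT-read fraction expected in non-carrier heterozygotes (mapping bias).
    lambda_expr: mean exon read count per wild-type chromosome per sample.
    baseline_intron: intron/exon coverage ratio in non-carriers (mis-splicing,
        pre-mRNA contamination), applied to all chromosomes.
    """

    s: float = 0.25
    rho: float = 0.5
    b: float = 0.5
    lambda_expr: float = 1000.0
    baseline_intron: float = 0.0067

    def __post_init__(self) -> None:
        for name in ("s", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.b < 1.0:
            raise InvalidArgumentError(f"b must be in (0,1), got {self.b}")
        if self.lambda_expr <= 0:
            raise InvalidArgumentError("lambda_expr must be positive")
        if self.baseline_intron < 0:
            raise InvalidArgumentError("baseline_intron must be non-negative")


def simulate_ase_counts(
    carrier_flags,
    params: FateModelParams,
    n_samples: int | None = None,
    seed: int = 0,
    noise: str = "poisson",
    nb_dispersion: float = 10.0,
) -> pd.DataFrame:
    """Simulate per-sample exon/intron and ALT/REF read counts.

    ``carrier_flags`` marks heterozygous carriers of the splice mutation; all
    samples are assumed heterozygous at the tagging SNP (only such samples
    are informative for allele-specific analysis).  Counts are Poisson by
    default, negative binomial (mean preserved, dispersion ``nb_dispersion``)
    on request.

    Returns a DataFrame with columns sample_id, carrier, exon_count,
    intron_count, alt_count, ref_count.
    """
    flags = np.asarray(carrier_flags, dtype=bool)
    if n_samples is None:
        n_samples = len(flags)
    if n_samples <= 0:
        raise InvalidArgumentError("n_samples must be positive")
    if len(flags) != n_samples:
        raise InvalidArgumentError("carrier_flags length does not match n_samples")
    if noise not in ("poisson", "negative_binomial"):
        raise InvalidArgumentError("noise must be 'poisson' or 'negative_binomial'")
    rng = np.random.default_rng(seed)

    lam = params.lambda_expr
    # per-chromosome exon emission rates; the tagging-SNP ALT allele rides the
    # mutant chromosome in carriers, and one of the two chromosomes (rate b
    # vs 1-b of the pair total) in non-carriers.
    mut_rate = np.where(flags, params.s * lam, lam)  # chromosome carrying the ALT tag
    wt_rate = np.full(n_samples, lam)

    exon_rate = mut_rate + wt_rate
    intron_rate = params.baseline_intron * exon_rate + np.where(
        flags, params.rho * params.s * lam, 0.0
    )
    # mapping bias tilts read recovery toward REF: ALT chromosome weighted by
    # b, REF chromosome by 1-b, so a balanced non-carrier shows ALT fraction b
    alt_rate = params.b * mut_rate
    ref_rate = (1 - params.b) * wt_rate

    def draw(mean: np.ndarray) -> np.ndarray:
        if noise == "poisson":
            return rng.poisson(mean)
        p = nb_dispersion / (nb_dispersion + mean)
        return rng.negative_binomial(nb_dispersion, np.clip(p, 1e-12, 1.0))

    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n_samples)],
            "carrier": flags.astype(int),
            "exon_count": draw(exon_rate),
            "intron_count": draw(intron_rate),
            "alt_count": draw(alt_rate),
            "ref_count": draw(ref_rate),
        }
    )
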