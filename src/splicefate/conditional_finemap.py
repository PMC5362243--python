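"""Stepwise conditional analysis: isolating independent signals in a region.

A gene-centered window (default 800 kb) is scanned by forward selection:
at each step every remaining variant is re-tested with the already-selected
variants' dosages as covariates in both the null and alternative models, and
the variant with the smallest conditional p-value that passes its
class-specific (or region-Bonferroni) significance threshold is added.
Selection stops when no variant passes.  LD between variants is tracked as
haplotype-level r^2 / D' so that selected signals can be required to be
effectively uncorrelated (the independence cap, r^2 < 0.02), and a
two-way conditional comparison adjudicates whether one variant's signal is
fully accounted for by another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import (
    AssocResult,
    KinshipWhitener,
    class_threshold,
    fit_lmm,
    fit_logistic,
    load_class_thresholds,
)
from .exceptions import (
    InvalidArgumentError,
    MonomorphicVariantError,
    SeparationError,
    UndefinedLdError,
)
from .synthetic_data.genotypes import HaplotypeSet, VariantPanel
from .synthetic_data.pedigree import KinshipMatrix

__all__ = [
    "CohortData",
    "RegionWindow",
    "ConditionalResult",
    "SignalSet",
    "ExplainsVerdict",
    "conditional_test",
    "stepwise_select",
    "pairwise_ld",
    "explains_signal",
]


@dataclass
class CohortData:
    """Aligned per-cohort analysis inputs.

    dosages: DataFrame (individuals x variants, values in [0,2]);
    exactly one of phenotype (quantitative) / status (binary) is set.
    haps supplies phase for exact LD; without it r^2 falls back to the
    squared dosage correlation and D' is unavailable.
    """

    dosages: pd.DataFrame
    panel: VariantPanel
    phenotype: np.ndarray | None = None
    status: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    phi: KinshipMatrix | None = None
    haps: HaplotypeSet | None = None
    _whitener: KinshipWhitener | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.phenotype is None) == (self.status is None):
            raise InvalidArgumentError("set exactly one of phenotype or status")
        n = len(self.dosages)
        vec = self.phenotype if self.phenotype is not None else self.status
        if len(vec) != n:
            raise InvalidArgumentError("trait vector not aligned with dosages")
        panel_ids = [v.id for v in self.panel.variants]
        if list(self.dosages.columns) != panel_ids:
            raise InvalidArgumentError("dosage columns must match panel variant ids, in order")

    @property
    def is_binary(self) -> bool:
        return self.status is not None

    @property
    def whitener(self) -> KinshipWhitener | None:
        if self.phi is not None and self._whitener is None:
            self._whitener = KinshipWhitener(self.phi)
        return self._whitener

    def variant(self, variant_id: str):
        for v in self.panel.variants:
            if v.id == variant_id:
                return v
        raise InvalidArgumentError(f"variant {variant_id!r} not in panel")

    @classmethod
    def from_haplotypes(cls, haps: HaplotypeSet, phenotype=None, status=None,
                        covariates=None, phi=None) -> "CohortData":
        dos = pd.DataFrame(
            haps.dosages, index=haps.ids, columns=[v.id for v in haps.panel.variants]
        )
        return cls(dos, haps.panel, phenotype=phenotype, status=status,
                   covariates=covariates, phi=phi, haps=haps)


@dataclass(frozen=True)
class RegionWindow:
    """A 1-based inclusive genomic window centered on an anchor gene."""

    chrom: str
    start: int
    end: int
    anchor_gene: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise InvalidArgumentError("invalid window bounds")

    @classmethod
    def centered(cls, chrom: str, midpoint: int, anchor_gene: str = "",
                 width: int = 800_000) -> "RegionWindow":
        start = max(1, midpoint - width // 2 + 1)
        return cls(chrom, start, start + width - 1, anchor_gene)

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class ConditionalResult:
    """Association of a target variant conditional on a set of others."""

    variant_id: str
    conditioned_on: tuple[str, ...]
    result: AssocResult | None
    collinear: bool = False
    error: str | None = None


def _conditional_design(cohort: CohortData, conditioned: tuple[str, ...]):
    cols = []
    if cohort.covariates is not None:
        cols.append(cohort.covariates.to_numpy(dtype=float))
    for vid in conditioned:
        cols.append(cohort.dosages[vid].to_numpy()[:, None])
    if not cols:
        return None
    return np.column_stack(cols)


def _is_collinear(target: np.ndarray, conditioned_dosages: np.ndarray) -> bool:
    x = np.column_stack([np.ones(len(target)), conditioned_dosages])
    beta, *_ = np.linalg.lstsq(x, target, rcond=None)
    resid = target - x @ beta
    tot = target.var()
    return tot == 0 or float(resid @ resid) / (len(target) * tot) < 1e-10


def conditional_test(
    target: str,
    conditioned,
    cohort: CohortData,
) -> ConditionalResult:
    """Test one variant with the conditioned variants as model covariates."""
    conditioned = tuple(conditioned)
    if target in conditioned:
        raise InvalidArgumentError("target cannot be in the conditioned set")
    g = cohort.dosages[target].to_numpy()
    if conditioned and _is_collinear(g, cohort.dosages[list(conditioned)].to_numpy()):
        return ConditionalResult(target, conditioned, None, collinear=True)
    covs = _conditional_design(cohort, conditioned)
    try:
        if cohort.is_binary:
            res = fit_logistic(cohort.status, g, covs, variant_id=target)
        else:
            res = fit_lmm(cohort.phenotype, g, covs,
                          phi=cohort.whitener, variant_id=target)
    except (MonomorphicVariantError, SeparationError, InvalidArgumentError) as exc:
        return ConditionalResult(target, conditioned, None, error=str(exc))
    return ConditionalResult(target, conditioned, res)


@dataclass
class SignalSet:
    """Forward-selected independent signals with the per-step audit trail."""

    selected: list[str]
    steps: list[dict]
    stopping_reason: str

    def __len__(self) -> int:
        return len(self.selected)


def stepwise_select(
    window: RegionWindow,
    cohort: CohortData,
    thresholds: dict[str, float] | None = None,
    bonferroni_m: int | None = None,
    independence_r2: float | None = 0.02,
    max_signals: int = 20,
    preselected: list[str] | None = None,
) -> SignalSet:
    """Forward stepwise conditional selection within a region window.

    Per-variant thresholds come from the class-threshold table unless
    ``bonferroni_m`` switches on region-Bonferroni mode (0.05/m for every
    variant).  With ``independence_r2`` set, candidates in LD above the cap
    with an already-selected variant are excluded, so the selected signals
    are pairwise effectively uncorrelated.  ``preselected`` seeds the
    conditioning set (its members are conditioned on but not re-reported).
    Deterministic: ties break by smaller p, then larger |beta|, then
    position.
    """
    table = thresholds if thresholds is not None else load_class_thresholds()
    in_window = [v for v in cohort.panel.variants if window.contains(v.chrom, v.pos)]
    if not in_window:
        raise InvalidArgumentError("window contains no panel variants")

    def threshold_for(v) -> float:
        if bonferroni_m is not None:
            return 0.05 / bonferroni_m
        return class_threshold(v.variant_class, table)

    base: list[str] = list(preselected or [])
    selected: list[str] = []
    steps: list[dict] = []
    reason = "max signals reached"
    for _ in range(max_signals):
        conditioning = base + selected
        candidates = [v for v in in_window if v.id not in conditioning]
        if independence_r2 is not None and conditioning:
            kept = []
            for v in candidates:
                r2s = [pairwise_r2(v.id, s, cohort) for s in conditioning]
                if max(r2s) < independence_r2:
                    kept.append(v)
            candidates = kept
        if not candidates:
            reason = "no candidates remaining"
            break
        fits = []
        for v in candidates:
            cres = conditional_test(v.id, tuple(conditioning), cohort)
            if cres.result is None:
                continue
            fits.append((v, cres.result))
        passers = [(v, r) for v, r in fits if r.p_raw <= threshold_for(v)]
        steps.append(
            {
                "conditioned_on": list(conditioning),
                "n_candidates": len(candidates),
                "n_passing": len(passers),
                "fits": {v.id: {"beta": r.beta, "se": r.se, "p": r.p_raw} for v, r in fits},
            }
        )
        if not passers:
            reason = "no variant passed threshold"
            break
        passers.sort(key=lambda vr: (vr[1].p_raw, -abs(vr[1].beta), vr[0].pos))
        best_v, best_r = passers[0]
        steps[-1]["selected"] = best_v.id
        steps[-1]["selected_p"] = best_r.p_raw
        selected.append(best_v.id)
    return SignalSet(selected, steps, reason)


def _hap_alleles(haps: HaplotypeSet, variant_id: str) -> np.ndarray:
    idx = [i for i, v in enumerate(haps.panel.variants) if v.id == variant_id]
    if not idx:
        raise InvalidArgumentError(f"variant {variant_id!r} not in panel")
    return haps.haplotypes[:, :, idx[0]].reshape(-1)


def pairwise_ld(a: str, b: str, haps: HaplotypeSet) -> tuple[float, float]:
    """Haplotype-level LD between two variants: (r^2, D').

    r^2 = D^2 / (pA pa pB pb); D' = |D| / D_max with the sign-dependent
    frequency bound on D.  Requires phased haplotypes and both variants
    polymorphic.
    """
    ha, hb = _hap_alleles(haps, a), _hap_alleles(haps, b)
    p_a, p_b = ha.mean(), hb.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise UndefinedLdError(f"variant {a if p_a in (0, 1) else b!r} is monomorphic")
    p_ab = np.mean(ha * hb)
    d = p_ab - p_a * p_b
    q_a, q_b = 1 - p_a, 1 - p_b
    r2 = d * d / (p_a * q_a * p_b * q_b)
    if d >= 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    dprime = 0.0 if d == 0 else abs(d) / d_max
    return float(r2), float(dprime)


def pairwise_r2(a: str, b: str, cohort: CohortData) -> float:
    """r^2 from phase when available, else squared dosage correlation."""
    if cohort.haps is not None:
        return pairwise_ld(a, b, cohort.haps)[0]
    da, db = cohort.dosages[a].to_numpy(), cohort.dosages[b].to_numpy()
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        raise UndefinedLdError("monomorphic variant")
    return float(np.corrcoef(da, db)[0, 1] ** 2)


@dataclass
class ExplainsVerdict:
    """Two-way conditional adjudication between variants a and b."""

    a: str
    b: str
    p_a_unconditional: float
    p_b_unconditional: float
    p_a_given_b: float | None
    p_b_given_a: float | None
    verdict: str


def explains_signal(a: str, b: str, cohort: CohortData, alpha: float = 0.05) -> ExplainsVerdict:
    """Decide whether one variant's association is accounted for by the other.

    "b explains a" iff a is no longer significant conditional on b while b
    stays significant conditional on a (and symmetrically); both conditional
    tests collinear means the variants are indistinguishable in this sample.
    """
    ua = conditional_test(a, (), cohort)
    ub = conditional_test(b, (), cohort)
    cab = conditional_test(a, (b,), cohort)  # a | b
    cba = conditional_test(b, (a,), cohort)  # b | a
    if cab.collinear and cba.collinear:
        verdict = "indistinguishable"
    elif cab.result is None or cba.result is None:
        verdict = "undetermined"
    else:
        a_gone = cab.result.p_raw > alpha
        b_gone = cba.result.p_raw > alpha
        if a_gone and not b_gone:
            verdict = "b explains a"
        elif b_gone and not a_gone:
            verdict = "a explains b"
        elif a_gone and b_gone:
            verdict = "mutually explained"
        else:
            verdict = "neither explains"
    return ExplainsVerdict(
        a, b,
        ua.result.p_raw if ua.result else np.nan,
        ub.result.p_raw if ub.result else np.nan,
        cab.result.p_raw if cab.result else None,
        cba.result.p_raw if cba.result else None,
        verdict,
    )
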