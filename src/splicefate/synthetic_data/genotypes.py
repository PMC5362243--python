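"""Variant panels, LD-structured haplotypes and gene-drop genotype simulation.

Founder haplotypes are drawn with block LD structure: within a block,
adjacent variants are coupled through two-locus haplotype frequencies whose
disequilibrium ``D`` is chosen to hit a target ``r^2`` (a Markov chain over
sites, so LD decays geometrically with block distance).  Non-founders
inherit haplotypes by gene dropping with recombination between adjacent
sites.  Phase is retained, so haplotype-level r^2/D' can be computed exactly
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..exceptions import InvalidArgumentError, LdConfigurationError
from .pedigree import Pedigree

__all__ = [
    "VARIANT_CLASSES",
    "VariantRecord",
    "LdBlock",
    "VariantPanel",
    "HaplotypeSet",
    "simulate_genotypes",
    "max_r2",
]

VARIANT_CLASSES = (
    "loss_of_function",
    "missense",
    "splice_region",
    "synonymous",
    "intronic",
    "intergenic",
    "upstream",
)


@dataclass(frozen=True)
class VariantRecord:
    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    allele_frequency: float
    variant_class: str = "intergenic"
    imputation_info: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_frequency < 1.0:
            raise InvalidArgumentError(
                f"allele_frequency must be in (0,1), got {self.allele_frequency}"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise InvalidArgumentError(f"unknown variant class {self.variant_class!r}")
        if not 0.0 <= self.imputation_info <= 1.0:
            raise InvalidArgumentError("imputation_info must be in [0,1]")


@dataclass(frozen=True)
class LdBlock:
    """Indices (into the panel) of variants coupled at target adjacent-pair r^2."""

    indices: tuple[int, ...]
    target_r2: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_r2 <= 1.0:
            raise InvalidArgumentError("target_r2 must be in [0,1]")


@dataclass
class VariantPanel:
    variants: list[VariantRecord]
    ld_blocks: list[LdBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, int] = {}
        for v in self.variants:
            prev = by_chrom.get(v.chrom)
            if prev is not None and v.pos <= prev:
                raise InvalidArgumentError(
                    f"positions must be strictly increasing within {v.chrom} (at {v.id})"
                )
            by_chrom[v.chrom] = v.pos
        covered = [i for b in self.ld_blocks for i in b.indices]
        if len(covered) != len(set(covered)):
            raise InvalidArgumentError("ld_blocks overlap")
        if covered and (min(covered) < 0 or max(covered) >= len(self.variants)):
            raise InvalidArgumentError("ld_block index out of range")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([v.allele_frequency for v in self.variants])

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])

    def blocks_with_singletons(self) -> list[LdBlock]:
        """All variants grouped: declared blocks plus singleton blocks."""
        covered = {i for b in self.ld_blocks for i in b.indices}
        blocks = list(self.ld_blocks)
        blocks += [LdBlock((i,), 0.0) for i in range(len(self.variants)) if i not in covered]
        return blocks


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes: array (n individuals, 2, n variants)."""

    ids: list[str]
    panel: VariantPanel
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.ids), 2, len(self.panel)):
            raise InvalidArgumentError("haplotype array shape mismatch")

    @property
    def dosages(self) -> np.ndarray:
        """Allele counts per individual x variant, values in {0,1,2}."""
        return self.haplotypes.sum(axis=1).astype(float)

    def dosage_of(self, variant_id: str) -> np.ndarray:
        idx = [i for i, v in enumerate(self.panel.variants) if v.id == variant_id]
        if not idx:
            raise InvalidArgumentError(f"variant {variant_id!r} not in panel")
        return self.dosages[:, idx[0]]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.reshape(-1, len(self.panel)).mean(axis=0)


def max_r2(p_a: float, p_b: float) -> float:
    """Frequency-constrained upper bound on r^2 for positively coupled loci."""
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    d_max = min(p_a * q_b, q_a * p_b)
    return d_max**2 / (p_a * q_a * p_b * q_b)


def _pair_d(p_a: float, p_b: float, r2: float) -> float:
    """Positive D achieving the target r^2, validated against the bound."""
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    bound = max_r2(p_a, p_b)
    if r2 > bound + 1e-12:
        raise LdConfigurationError(
            f"target r2={r2:.4g} exceeds r2_max={bound:.4g} for allele "
            f"frequencies {p_a:.4g}, {p_b:.4g}"
        )
    return float(np.sqrt(r2 * p_a * q_a * p_b * q_b))


def _founder_block_haplotypes(
    freqs: np.ndarray, target_r2: float, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    """Markov-chain haplotype draws hitting target r^2 between adjacent sites."""
    m = len(freqs)
    out = np.empty((n_hap, m), dtype=np.int8)
    out[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, m):
        p_a, p_b = float(freqs[j - 1]), float(freqs[j])
        d = _pair_d(p_a, p_b, target_r2)
        # conditional P(B=1 | A) from two-locus haplotype frequencies
        p_b_given_1 = np.clip((p_a * p_b + d) / p_a, 0.0, 1.0)
        p_b_given_0 = np.clip(((1 - p_a) * p_b - d) / (1 - p_a), 0.0, 1.0)
        cond = np.where(out[:, j - 1] == 1, p_b_given_1, p_b_given_0)
        out[:, j] = rng.random(n_hap) < cond
    return out


def simulate_genotypes(
    ped: Pedigree,
    panel: VariantPanel,
    recomb_rate: float = 1e-8,
    seed: int = 0,
) -> HaplotypeSet:
    """Gene-drop simulation of phased haplotypes over a pedigree.

    Founder haplotypes come from the block-LD construction; each child
    haplotype is a recombinant mosaic of the transmitting parent's two
    haplotypes, with crossover probability ``min(0.5, recomb_rate * distance)``
    between adjacent panel sites.
    """
    if len(panel) == 0:
        raise InvalidArgumentError("panel must be non-empty")
    if recomb_rate < 0:
        raise InvalidArgumentError("recomb_rate must be non-negative")
    rng = np.random.default_rng(seed)
    m = len(panel)
    founders = ped.founders()
    n_founder_hap = 2 * len(founders)

    founder_haps = np.empty((n_founder_hap, m), dtype=np.int8)
    for block in panel.blocks_with_singletons():
        idx = np.array(block.indices)
        founder_haps[:, idx] = _founder_block_haplotypes(
            panel.frequencies[idx], block.target_r2, n_founder_hap, rng
        )

    # switch probabilities between consecutive panel sites (same chrom only)
    positions = panel.positions
    chroms = [v.chrom for v in panel.variants]
    switch = np.zeros(m)
    for j in range(1, m):
        if chroms[j] == chroms[j - 1]:
            switch[j] = min(0.5, recomb_rate * abs(positions[j] - positions[j - 1]))
        else:
            switch[j] = 0.5

    haps = np.empty((len(ped), 2, m), dtype=np.int8)
    pos = {s: i for i, s in enumerate(ped.ids)}
    founder_cursor = 0
    for i, ind in enumerate(ped.individuals):
        if ind.is_founder:
            haps[i, 0] = founder_haps[founder_cursor]
            haps[i, 1] = founder_haps[founder_cursor + 1]
            founder_cursor += 2
        else:
            for h, parent_id in enumerate((ind.father_id, ind.mother_id)):
                parent = haps[pos[parent_id]]
                flips = rng.random(m) < switch
                flips[0] = rng.integers(2)  # which parental haplotype starts
                source = np.cumsum(flips) & 1
                haps[i, h] = parent[source, np.arange(m)]
    return HaplotypeSet(ped.ids, panel, haps)
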