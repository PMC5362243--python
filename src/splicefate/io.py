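"""File formats: VCF (DS/GT), PED, kinship/phenotype/ASE/cohort TSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .exceptions import InvalidArgumentError
from .synthetic_data.genotypes import HaplotypeSet
from .synthetic_data.pedigree import KinshipMatrix, Pedigree


def write_vcf(haps: HaplotypeSet, path: str | Path) -> None:
    """Write phased genotypes as uncompressed VCF 4.2 with GT and DS fields."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">')
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">')
    header.add_line('##INFO=<ID=CLASS,Number=1,Type=String,Description="Variant class">')
    header.add_line('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info">')
    for chrom in dict.fromkeys(v.chrom for v in haps.panel.variants):
        header.contigs.add(chrom)
    for sid in haps.ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, v in enumerate(haps.panel.variants):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref, v.alt), id=v.id,
            )
            rec.info["AF"] = v.allele_frequency
            rec.info["CLASS"] = v.variant_class
            rec.info["INFO"] = v.imputation_info
            for i, sid in enumerate(haps.ids):
                a, b = int(haps.haplotypes[i, 0, j]), int(haps.haplotypes[i, 1, j])
                rec.samples[sid]["GT"] = (a, b)
                rec.samples[sid].phased = True
                rec.samples[sid]["DS"] = float(a + b)
            vcf.write(rec)


def read_dosages(path: str | Path) -> pd.DataFrame:
    """Read per-sample dosages from a VCF (DS field, GT allele-count fallback).

    Returns a DataFrame (samples x variants).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            cols[vid] = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(rec.genotype.array())[:, :2]
            cols[vid] = np.where(gt < 0, np.nan, gt).sum(axis=1).astype(float)
    vcf.close()
    if not cols:
        raise InvalidArgumentError(f"no variant records in {path}")
    return pd.DataFrame(cols, index=samples)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write a PED-like 6-column TSV (family, id, father, mother, sex, generation)."""
    rows = [
        (ind.family_id, ind.id, ind.father_id or "0", ind.mother_id or "0",
         ind.sex, ind.generation)
        for ind in ped
    ]
    pd.DataFrame(
        rows, columns=["family_id", "id", "father_id", "mother_id", "sex", "generation"]
    ).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    from .synthetic_data.pedigree import Individual

    df = pd.read_csv(path, sep="\t", dtype=str)
    inds = [
        Individual(
            r.id,
            None if r.father_id in ("0", None) else r.father_id,
            None if r.mother_id in ("0", None) else r.mother_id,
            int(r.sex),
            r.family_id,
            int(getattr(r, "generation", 0) or 0),
        )
        for r in df.itertuples(index=False)
    ]
    return Pedigree(inds)


def write_kinship(phi: KinshipMatrix, path: str | Path) -> None:
    """Square kinship TSV with id header row and index column."""
    pd.DataFrame(phi.phi, index=phi.ids, columns=phi.ids).to_csv(path, sep="\t")


def read_kinship(path: str | Path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise InvalidArgumentError("kinship TSV row/column ids disagree")
    return KinshipMatrix(list(df.index), df.to_numpy(dtype=float))


def write_phenotypes(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_ase(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_ase(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "carrier", "exon_count", "intron_count", "alt_count", "ref_count"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"ASE table missing columns: {sorted(missing)}")
    return df


def read_cohort_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"cohort", "scale", "estimate", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"cohort table missing columns: {sorted(missing)}")
    return df
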