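"""Phenotype standardization: rank-based inverse-normal transform + covariate adjustment.

Quantitative trait values (e.g. blood eosinophil counts, cells/ul) are mapped
onto a standard normal scale by quantile-quantile standardization — each value
is replaced by the normal quantile of its rank, Phi^-1(rank/(n+1)), with
average ranks for ties — and then adjusted for covariates (sex, year of
birth, age at measurement) by taking least-squares residuals.  The order of
operations is standardize first, then residualize, optionally restandardize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CollinearityError,
    DegeneratePhenotypeError,
    InvalidArgumentError,
)

__all__ = ["PhenotypeVector", "qq_standardize", "adjust_covariates", "prepare_phenotype"]


@dataclass
class PhenotypeVector:
    """A phenotype on the SD scale together with its provenance."""

    ids: list[str]
    raw_values: np.ndarray
    standardized_values: np.ndarray
    adjustment_covariates: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "raw": self.raw_values, "standardized": self.standardized_values}
        )


def qq_standardize(values, offset: str = "vdw") -> np.ndarray:
    """Quantile-quantile standardization to a standard normal scale.

    Values are replaced by Phi^-1(r_i/(n+1)) where r_i is the average rank
    (Van der Waerden quantiles; ``offset='blom'`` uses (r_i - 3/8)/(n + 1/4)).
    Ties share a quantile; an all-tied vector maps to all zeros.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InvalidArgumentError("empty input")
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise InvalidArgumentError(f"non-finite values at indices {bad.tolist()}")
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 observations")
    ranks = stats.rankdata(x, method="average")
    if offset == "vdw":
        q = ranks / (x.size + 1.0)
    elif offset == "blom":
        q = (ranks - 0.375) / (x.size + 0.25)
    else:
        raise InvalidArgumentError(f"unknown offset rule {offset!r}")
    return stats.norm.ppf(q)


def adjust_covariates(
    z,
    covariates: pd.DataFrame,
    restandardize: bool = True,
) -> np.ndarray:
    """Residualize a standardized phenotype on covariates (with intercept).

    Raises CollinearityError naming the offending columns on a rank-deficient
    design, DegeneratePhenotypeError if the fit leaves no residual variance.
    """
    z = np.asarray(z, dtype=float)
    if len(covariates) != z.size:
        raise InvalidArgumentError("covariates not aligned with phenotype")
    X = np.column_stack([np.ones(z.size), covariates.to_numpy(dtype=float)])
    names = ["intercept"] + list(covariates.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns not adding rank, scanning left to right
        offending = []
        kept = X[:, [0]]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                offending.append(names[j])
            else:
                kept = cand
        raise CollinearityError(
            f"rank-deficient covariate design; offending columns: {offending}", offending
        )
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    sd = resid.std(ddof=0)
    if sd < 1e-10:
        raise DegeneratePhenotypeError("phenotype is an exact linear function of covariates")
    return resid / sd if restandardize else resid


def prepare_phenotype(
    ids,
    raw_values,
    covariates: pd.DataFrame | None = None,
    restandardize: bool = True,
    offset: str = "vdw",
) -> PhenotypeVector:
    """Standardize then adjust, returning a PhenotypeVector ready for association."""
    z = qq_standardize(raw_values, offset=offset)
    names: list[str] = []
    if covariates is not None and covariates.shape[1] > 0:
        z = adjust_covariates(z, covariates, restandardize=restandardize)
        names = list(covariates.columns)
    return PhenotypeVector(list(ids), np.asarray(raw_values, float), z, names)
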