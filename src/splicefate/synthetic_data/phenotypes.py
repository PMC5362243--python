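"""Quantitative and binary phenotype simulation over family-structured genotypes.

Quantitative traits follow the generating model

    y = alpha + X gamma + sum_v beta_v g_v + u + e,

where ``u`` is a polygenic family effect with covariance proportional to the
relationship matrix ``2 Phi`` and ``e`` is i.i.d. noise; the two variance
components are scaled so the total residual (non-genotype) variance is 1 in
expectation, with ``h2_family`` of it attributable to the family term.
Binary traits are Bernoulli under a logistic model with per-variant odds
ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..exceptions import AlignmentError, InvalidArgumentError
from .genotypes import HaplotypeSet
from .pedigree import KinshipMatrix

__all__ = [
    "simulate_covariates",
    "simulate_quantitative_phenotype",
    "simulate_case_control",
    "sample_family_effect",
]


def sample_family_effect(phi: KinshipMatrix, rng: np.random.Generator) -> np.ndarray:
    """Draw u ~ N(0, 2*Phi) exploiting block-diagonal family structure."""
    u = np.empty(len(phi.ids))
    for idx in phi.block_indices():
        k = 2.0 * phi.dense_block(idx)
        if len(idx) == 1:
            u[idx] = rng.normal(scale=np.sqrt(k[0, 0]))
        else:
            chol = np.linalg.cholesky(k + 1e-10 * np.eye(len(idx)))
            u[idx] = chol @ rng.standard_normal(len(idx))
    return u


def simulate_covariates(ids, rng: np.random.Generator) -> pd.DataFrame:
    """Independent sex (binary) and age (uniform 18-90) covariates."""
    n = len(ids)
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n).astype(float),
            "age": rng.uniform(18.0, 90.0, n),
        },
        index=list(ids),
    )


def _aligned_dosage_effects(haps: HaplotypeSet, effects: dict[str, float]) -> np.ndarray:
    dosages = haps.dosages
    contrib = np.zeros(len(haps.ids))
    panel_ids = [v.id for v in haps.panel.variants]
    for vid, eff in effects.items():
        if vid not in panel_ids:
            raise InvalidArgumentError(f"effect refers to unknown variant {vid!r}")
        contrib += eff * dosages[:, panel_ids.index(vid)]
    return contrib


def simulate_quantitative_phenotype(
    haps: HaplotypeSet,
    effects: dict[str, float],
    phi: KinshipMatrix | None = None,
    h2_family: float = 0.0,
    covariate_effects: dict[str, float] | None = None,
    alpha: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a standardized quantitative trait with family covariance.

    Returns a DataFrame indexed by individual id with a ``phenotype`` column
    and any simulated covariate columns.  ``effects`` maps variant ids to
    per-allele effects in SD units; ``h2_family`` is the fraction of residual
    variance from the polygenic family term.
    """
    if not 0.0 <= h2_family < 1.0:
        raise InvalidArgumentError("h2_family must be in [0,1)")
    rng = np.random.default_rng(seed)
    n = len(haps.ids)

    if h2_family > 0:
        if phi is None:
            raise InvalidArgumentError("h2_family > 0 requires a kinship matrix")
        if list(phi.ids) != list(haps.ids):
            raise AlignmentError("kinship ids do not match haplotype ids")
        u = np.sqrt(h2_family) * sample_family_effect(phi, rng)
    else:
        u = np.zeros(n)
    e = np.sqrt(1.0 - h2_family) * rng.standard_normal(n)

    covs = simulate_covariates(haps.ids, rng)
    fixed = np.zeros(n)
    if covariate_effects:
        for name, eff in covariate_effects.items():
            if name not in covs.columns:
                raise InvalidArgumentError(f"unknown covariate {name!r}")
            fixed += eff * covs[name].to_numpy()

    y = alpha + fixed + _aligned_dosage_effects(haps, effects) + u + e
    out = covs.copy()
    out.insert(0, "phenotype", y)
    return out


def simulate_case_control(
    haps: HaplotypeSet,
    ors: dict[str, float],
    baseline_prevalence: float,
    covariate_effects: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli case/control labels under a logistic model.

    P(case) = logistic(logit(baseline_prevalence) + sum_v log(OR_v) g_v + X gamma).
    """
    if not 0.0 < baseline_prevalence < 1.0:
        raise InvalidArgumentError("baseline_prevalence must be in (0,1)")
    for vid, o in ors.items():
        if o <= 0:
            raise InvalidArgumentError(f"odds ratio for {vid!r} must be positive")
    rng = np.random.default_rng(seed)

    log_effects = {vid: np.log(o) for vid, o in ors.items()}
    eta = np.log(baseline_prevalence / (1 - baseline_prevalence))
    eta = eta + _aligned_dosage_effects(haps, log_effects)

    covs = simulate_covariates(haps.ids, rng)
    if covariate_effects:
        for name, eff in covariate_effects.items():
            if name not in covs.columns:
                raise InvalidArgumentError(f"unknown covariate {name!r}")
            eta = eta + eff * covs[name].to_numpy()

    p = 1.0 / (1.0 + np.exp(-eta))
    status = (rng.random(len(haps.ids)) < p).astype(int)
    out = covs.copy()
    out.insert(0, "status", status)
    return out
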