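"""Variant-phenotype association under a kinship mixed model.

Quantitative traits: y ~ N(alpha + beta*g + X*gamma, 2*sigma^2*Phi) with Phi
the pedigree kinship matrix, treated as known.  The fit decorrelates the data
with a Cholesky factorization of 2*Phi (block-wise over families, so cohorts
of many small families cost O(n) rather than O(n^3)), profiles sigma^2 by
maximum likelihood, and tests beta with the likelihood-ratio statistic
against the model omitting g.  Binary traits use logistic regression with
nuisance covariates, again LRT-tested.  Genome-wide inflation from residual
relatedness/stratification is removed by dividing chi^2 statistics by the
LD-score-regression intercept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .exceptions import (
    AlignmentError,
    ConfigurationError,
    InvalidArgumentError,
    MonomorphicVariantError,
    SeparationError,
)
from .synthetic_data.genotypes import VARIANT_CLASSES
from .synthetic_data.pedigree import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "KinshipWhitener",
    "fit_lmm",
    "fit_logistic",
    "LdScoreFit",
    "ld_score_regression_intercept",
    "apply_genomic_control",
    "class_threshold",
    "bonferroni_threshold",
    "load_class_thresholds",
]


@dataclass
class AssocResult:
    """One variant's association summary.

    beta is in SD units for quantitative traits and log-odds for binary
    traits (or_ = exp(beta) then); p_corrected is populated by
    apply_genomic_control.
    """

    variant_id: str
    beta: float
    se: float
    chi2_lrt: float
    p_raw: float
    n: int
    or_: float | None = None
    p_corrected: float | None = None
    chi2_corrected: float | None = None

    def to_dict(self) -> dict:
        return {
            "variant": self.variant_id,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_,
            "chi2": self.chi2_lrt,
            "p_raw": self.p_raw,
            "p_corrected": self.p_corrected,
            "n": self.n,
        }


class KinshipWhitener:
    """Reusable spectral factorization of the relationship matrix K = 2*Phi.

    Families are independent, so K is block diagonal up to ordering; each
    block is eigendecomposed (K = U diag(lam) U') and U assembled as one
    sparse matrix.  In the rotated basis U'y the model covariance
    sigma^2 [(1-c) I + c K] is diagonal for any variance-component mixing
    ratio c, so profiling c by ML costs O(n) per likelihood evaluation.
    Reuse one instance across many fits on the same cohort (e.g. a regional
    scan) to amortize the decomposition.
    """

    def __init__(self, phi: KinshipMatrix):
        self.n = len(phi.ids)
        self.ids = list(phi.ids)
        lam = np.empty(self.n)
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        offset = 0
        for idx in phi.block_indices():
            kb = 2.0 * phi.dense_block(idx)
            w, u = np.linalg.eigh(kb)
            if w[0] <= 1e-10:
                raise InvalidArgumentError("2*Phi is not positive definite; cannot whiten")
            m = len(idx)
            lam[offset:offset + m] = w
            r, c = np.nonzero(u)
            rows.append(idx[r])
            cols.append(offset + c)
            vals.append(u[r, c])
            offset += m
        from scipy.sparse import coo_matrix

        # column j of U holds the eigenvector with eigenvalue lam[j]
        self._u = coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        ).tocsr()
        self.eigenvalues = lam

    def rotate(self, a: np.ndarray) -> np.ndarray:
        """Apply U' to a vector or the columns of a matrix."""
        return self._u.T @ np.asarray(a, dtype=float)

    def variances(self, c: float) -> np.ndarray:
        """Diagonal of the rotated covariance (up to sigma^2) at mixing ratio c."""
        return (1.0 - c) + c * self.eigenvalues

    def whiten(self, a: np.ndarray, c: float = 1.0) -> np.ndarray:
        """Decorrelate: rows scaled to unit variance under [(1-c)I + cK]."""
        return self.rotate(a) / np.sqrt(self.variances(c))[
            (slice(None),) + (None,) * (np.ndim(a) - 1)
        ]


def _design(n: int, covariates) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None:
        c = covariates.to_numpy(dtype=float) if hasattr(covariates, "to_numpy") else np.asarray(
            covariates, dtype=float
        )
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise AlignmentError("covariates not aligned with phenotype")
        cols.append(c)
    return np.column_stack(cols)


def _profile_ols(w_y: np.ndarray, w_x: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """OLS on whitened data; returns (coef, rss, XtX_inv)."""
    xtx = w_x.T @ w_x
    try:
        fac = cho_factor(xtx)
    except np.linalg.LinAlgError as exc:
        raise InvalidArgumentError("design matrix is rank deficient") from exc
    coef = cho_solve(fac, w_x.T @ w_y)
    resid = w_y - w_x @ coef
    return coef, float(resid @ resid), np.linalg.inv(xtx)


def _ml_mixing_ratio(rot_y: np.ndarray, rot_x: np.ndarray, whitener: KinshipWhitener) -> float:
    """ML estimate of the variance-component mixing ratio c in [0, 1).

    The profile (over coefficients and sigma^2) negative log-likelihood of
    the rotated null model is minimized over c; one evaluation is O(n).
    """
    from scipy.optimize import minimize_scalar

    n = rot_y.size

    def neg_ll(c: float) -> float:
        v = whitener.variances(c)
        sw = 1.0 / np.sqrt(v)
        _, rss, _ = _profile_ols(rot_y * sw, rot_x * sw[:, None])
        return n * np.log(rss / n) + np.log(v).sum()

    res = minimize_scalar(neg_ll, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def fit_lmm(
    y,
    g,
    covariates=None,
    phi: KinshipMatrix | KinshipWhitener | None = None,
    variant_id: str = "variant",
    variance_ratio: float | str = "ml",
) -> AssocResult:
    """Kinship-aware mixed-model association test for a quantitative trait.

    The covariance is sigma^2 [(1-c) I + c * 2*Phi]; ``variance_ratio``
    fixes the mixing ratio c (1.0 gives the pure 2*sigma^2*Phi model) or,
    with "ml" (default), estimates it by maximum likelihood under the null
    model and holds it fixed for the LRT — the standard two-stage
    mixed-model GWAS scheme.  sigma^2 is profiled analytically; with phi
    None (or 2*Phi = I) the fit collapses to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.size
    if g.size != n:
        raise AlignmentError("genotype vector not aligned with phenotype")
    if np.ptp(g) == 0:
        raise MonomorphicVariantError(f"variant {variant_id!r} is monomorphic in this sample")

    x_null = _design(n, covariates)
    x_full = np.column_stack([x_null, g])

    if phi is None:
        w_y, w_null, w_full = y, x_null, x_full
    else:
        whitener = phi if isinstance(phi, KinshipWhitener) else KinshipWhitener(phi)
        if whitener.n != n:
            raise AlignmentError("kinship matrix not aligned with phenotype")
        rot_y = whitener.rotate(y)
        rot_null = whitener.rotate(x_null)
        if variance_ratio == "ml":
            c = _ml_mixing_ratio(rot_y, rot_null, whitener)
        else:
            c = float(variance_ratio)
            if not 0.0 <= c <= 1.0:
                raise InvalidArgumentError("variance_ratio must be in [0,1] or 'ml'")
        sw = 1.0 / np.sqrt(whitener.variances(c))
        w_y = rot_y * sw
        w_null = rot_null * sw[:, None]
        w_full = whitener.rotate(x_full) * sw[:, None]

    coef, rss_full, xtx_inv = _profile_ols(w_y, w_full)
    _, rss_null, _ = _profile_ols(w_y, w_null)
    if rss_full <= 0:
        raise InvalidArgumentError("zero residual variance in full model")

    sigma2 = rss_full / n  # ML profile estimate
    beta = float(coef[-1])
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    chi2_lrt = float(max(0.0, n * np.log(rss_null / rss_full)))
    p_raw = float(stats.chi2.sf(chi2_lrt, df=1))
    return AssocResult(variant_id, beta, se, chi2_lrt, p_raw, n)


def fit_logistic(status, g, covariates=None, variant_id: str = "variant") -> AssocResult:
    """Logistic-regression association test for a binary trait (LRT)."""
    status = np.asarray(status, dtype=float)
    g = np.asarray(g, dtype=float)
    n = status.size
    if g.size != n:
        raise AlignmentError("genotype vector not aligned with status")
    classes = np.unique(status)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise InvalidArgumentError("status must be 0/1")
    if classes.size < 2:
        raise InvalidArgumentError("both cases and controls required")
    if np.ptp(g) == 0:
        raise MonomorphicVariantError(f"variant {variant_id!r} is monomorphic in this sample")

    x_null = _design(n, covariates)
    x_full = np.column_stack([x_null, g])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            full = sm.Logit(status, x_full).fit(disp=0, maxiter=200)
            null = sm.Logit(status, x_null).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"complete separation for variant {variant_id!r}") from exc
    if not np.all(np.isfinite(full.bse)) or np.abs(full.params[-1]) > 30:
        raise SeparationError(f"quasi-complete separation for variant {variant_id!r}")

    beta = float(full.params[-1])
    se = float(full.bse[-1])
    chi2_lrt = float(max(0.0, 2.0 * (full.llf - null.llf)))
    p_raw = float(stats.chi2.sf(chi2_lrt, df=1))
    return AssocResult(variant_id, beta, se, chi2_lrt, p_raw, n, or_=float(np.exp(beta)))


@dataclass
class LdScoreFit:
    intercept: float
    intercept_se: float
    slope: float
    n_variants: int


def ld_score_regression_intercept(
    chi2_stats, ld_scores, min_variants: int = 100
) -> LdScoreFit:
    """Intercept of the regression of per-variant chi^2 on LD score.

    The intercept estimates the inflation of test statistics from
    relatedness/stratification (polygenic signal loads on the slope); it is
    used as the genomic-control divisor.  Unweighted OLS.
    """
    c = np.asarray(chi2_stats, dtype=float)
    s = np.asarray(ld_scores, dtype=float)
    if c.size != s.size:
        raise AlignmentError("chi2 and LD-score vectors differ in length")
    ok = np.isfinite(c) & np.isfinite(s)
    c, s = c[ok], s[ok]
    if c.size < min_variants:
        raise InvalidArgumentError(f"need >= {min_variants} variants, got {c.size}")
    if np.ptp(s) == 0:
        raise InvalidArgumentError("LD scores have zero variance")
    x = sm.add_constant(s)
    fit = sm.OLS(c, x).fit()
    return LdScoreFit(float(fit.params[0]), float(fit.bse[0]), float(fit.params[1]), int(c.size))


def apply_genomic_control(results, lambda_: float) -> list[AssocResult]:
    """Divide chi^2 statistics by lambda and recompute p-values.

    lambda <= 1 would inflate significance, so the raw p-values are kept
    (with a logged note), matching the convention that genomic control only
    ever deflates test statistics.
    """
    if lambda_ <= 0:
        raise InvalidArgumentError("lambda must be positive")
    if lambda_ <= 1.0:
        logger.info("lambda=%.4f <= 1; genomic control left p-values unchanged", lambda_)
    out = []
    for r in results:
        if lambda_ <= 1.0:
            chi2_c, p_c = r.chi2_lrt, r.p_raw
        else:
            chi2_c = r.chi2_lrt / lambda_
            p_c = float(stats.chi2.sf(chi2_c, df=1))
        out.append(
            AssocResult(
                r.variant_id, r.beta, r.se, r.chi2_lrt, r.p_raw, r.n,
                or_=r.or_, p_corrected=p_c, chi2_corrected=chi2_c,
            )
        )
    return out


def load_class_thresholds(path=None) -> dict[str, float]:
    """Per-class genome-wide significance thresholds (config-overridable)."""
    if path is None:
        ref = resources.files("splicefate").joinpath("config/class_thresholds.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table = {str(k): float(v) for k, v in raw["class_thresholds"].items()}
    unknown = set(table) - set(VARIANT_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown classes in threshold config: {sorted(unknown)}")
    missing = set(VARIANT_CLASSES) - set(table)
    if missing:
        raise ConfigurationError(f"threshold config missing classes: {sorted(missing)}")
    return table


def class_threshold(variant_class: str, config: dict[str, float] | None = None) -> float:
    """Significance threshold for a variant, by functional-impact class.

    Higher-impact classes get larger (less stringent) thresholds, weighting
    variants by their prior probability of affecting gene function.
    """
    table = config if config is not None else load_class_thresholds()
    if variant_class not in table:
        raise ConfigurationError(
            f"unknown variant class {variant_class!r}; known: {sorted(table)}"
        )
    return table[variant_class]


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Region-wide Bonferroni threshold alpha/m (e.g. 0.05/17935 = 2.79e-6)."""
    if n_tests <= 0:
        raise InvalidArgumentError("n_tests must be positive")
    return alpha / n_tests
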