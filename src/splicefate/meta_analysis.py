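"""Inverse-variance meta-analysis of per-cohort effect estimates.

Cohort effects arrive as point estimates with 95% CIs, either odds ratios
(combined on the log-odds scale) or SD-unit effects.  The default model is
fixed-effect: weights w_i = 1/SE_i^2, combined effect sum(w_i theta_i) /
sum(w_i), SE 1/sqrt(sum w_i).  Heterogeneity is summarized by Cochran's
Q = sum w_i (theta_i - theta_bar)^2 on k-1 degrees of freedom and
I^2 = max(0, (Q - df)/Q) * 100.  A DerSimonian-Laird random-effects variant
is available but never the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError

__all__ = [
    "Z_95",
    "CohortEstimate",
    "MetaResult",
    "se_from_ci",
    "fixed_effect_meta",
    "random_effects_meta",
    "heterogeneity",
    "cohorts_from_frame",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class CohortEstimate:
    """One cohort's effect on its reported scale (OR for log_odds)."""

    cohort: str
    scale: str  # "log_odds" or "sd_units"
    estimate: float
    ci_low: float
    ci_high: float
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("log_odds", "sd_units"):
            raise InvalidArgumentError(f"unknown scale {self.scale!r}")
        if not self.ci_low < self.estimate < self.ci_high:
            raise InvalidArgumentError(
                f"{self.cohort}: CI ({self.ci_low}, {self.ci_high}) must bracket "
                f"estimate {self.estimate}"
            )

    @property
    def theta(self) -> float:
        """Effect on the linear combination scale (log-odds for ORs)."""
        if self.scale == "log_odds":
            return float(np.log(self.estimate))
        return float(self.estimate)

    @property
    def se(self) -> float:
        return se_from_ci(self.estimate, self.ci_low, self.ci_high, self.scale)


@dataclass
class MetaResult:
    """Combined estimate on the reported scale, with heterogeneity statistics."""

    scale: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    q: float | None = None
    df: int | None = None
    p_het: float | None = None
    i2: float | None = None
    method: str = "fixed_effect"

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "q": self.q,
            "df": self.df,
            "p_het": self.p_het,
            "i2": self.i2,
            "method": self.method,
        }


def se_from_ci(estimate: float, ci_low: float, ci_high: float, scale: str) -> float:
    """Back-derive the standard error from a 95% CI.

    On the log-odds scale SE = (ln hi - ln lo) / (2 * 1.959964); on the SD
    scale the same with raw bounds.
    """
    if ci_low >= ci_high:
        raise InvalidArgumentError("ci_low must be below ci_high")
    if scale == "log_odds":
        if ci_low <= 0 or estimate <= 0:
            raise InvalidArgumentError("OR and CI bounds must be positive on the log scale")
        return float((np.log(ci_high) - np.log(ci_low)) / (2 * Z_95))
    if scale == "sd_units":
        return float((ci_high - ci_low) / (2 * Z_95))
    raise InvalidArgumentError(f"unknown scale {scale!r}")


def _check(estimates: list[CohortEstimate]) -> tuple[np.ndarray, np.ndarray, str]:
    if not estimates:
        raise InvalidArgumentError("need at least one cohort estimate")
    scales = {e.scale for e in estimates}
    if len(scales) > 1:
        raise InvalidArgumentError(f"mixed scales: {sorted(scales)}")
    theta = np.array([e.theta for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(se <= 0):
        raise InvalidArgumentError("zero or negative SE")
    return theta, se, scales.pop()


def _back(scale: str, value: float) -> float:
    return float(np.exp(value)) if scale == "log_odds" else float(value)


def fixed_effect_meta(estimates: list[CohortEstimate]) -> MetaResult:
    """Fixed-effect inverse-variance combination, with heterogeneity when k >= 2."""
    theta, se, scale = _check(estimates)
    w = 1.0 / se**2
    combined = float(np.sum(w * theta) / np.sum(w))
    se_c = float(1.0 / np.sqrt(np.sum(w)))
    z = combined / se_c
    p = float(2 * stats.norm.sf(abs(z)))
    res = MetaResult(
        scale,
        _back(scale, combined),
        _back(scale, combined - Z_95 * se_c),
        _back(scale, combined + Z_95 * se_c),
        p,
    )
    if len(estimates) >= 2:
        res.q, res.df, res.p_het, res.i2 = heterogeneity(estimates)
    return res


def heterogeneity(estimates: list[CohortEstimate]) -> tuple[float, int, float, float]:
    """Cochran's Q, df, its chi^2 p-value and I^2 (percent, clipped at 0)."""
    if len(estimates) < 2:
        raise InvalidArgumentError("heterogeneity needs >= 2 cohorts")
    theta, se, _ = _check(estimates)
    w = 1.0 / se**2
    combined = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - combined) ** 2))
    df = len(estimates) - 1
    p_het = float(stats.chi2.sf(q, df))
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return q, df, p_het, i2


def random_effects_meta(estimates: list[CohortEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects combination (optional, never default)."""
    theta, se, scale = _check(estimates)
    if len(estimates) < 2:
        return fixed_effect_meta(estimates)
    q, df, p_het, i2 = heterogeneity(estimates)
    w = 1.0 / se**2
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    combined = float(np.sum(w_star * theta) / np.sum(w_star))
    se_c = float(1.0 / np.sqrt(np.sum(w_star)))
    p = float(2 * stats.norm.sf(abs(combined / se_c)))
    return MetaResult(
        scale,
        _back(scale, combined),
        _back(scale, combined - Z_95 * se_c),
        _back(scale, combined + Z_95 * se_c),
        p,
        q=q, df=df, p_het=p_het, i2=i2,
        method="random_effects_dl",
    )


def cohorts_from_frame(frame: pd.DataFrame) -> list[CohortEstimate]:
    """Build CohortEstimates from a TSV-shaped frame.

    Expected columns: cohort, scale, estimate, ci_low, ci_high and optional
    n, n_cases, n_controls.
    """
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            CohortEstimate(
                cohort=str(row.cohort),
                scale=str(row.scale),
                estimate=float(row.estimate),
                ci_low=float(row.ci_low),
                ci_high=float(row.ci_high),
                n=int(row.n) if hasattr(row, "n") and pd.notna(row.n) else None,
                n_cases=int(row.n_cases) if hasattr(row, "n_cases") and pd.notna(row.n_cases) else None,
                n_controls=int(row.n_controls)
                if hasattr(row, "n_controls") and pd.notna(row.n_controls) else None,
            )
        )
    return out
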