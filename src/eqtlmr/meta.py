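"""Fixed-effect inverse-variance meta-analysis of study-level MR estimates.

Published cohort results often arrive only as an odds ratio with a 95% CI;
``se_from_ci`` recovers the log-scale standard error from the CI width
(using the normal quantile 1.959964), after which ``fixed_effect_meta``
combines the studies with weights 1/se².  Cochran's Q and I² are reported as
standard companion heterogeneity diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import logger

Z_95 = 1.959964


@dataclass
class StudyEstimate:
    """One cohort's estimate on the additive (log-OR or trait-unit) scale."""

    study: str
    beta: float
    se: float
    k: int | None = None
    cases: int | None = None
    controls: int | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.study}: se must be > 0, got {self.se}")


@dataclass
class MetaResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    z: float
    q_statistic: float
    i2: float
    n_studies: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["odds_ratio"] = self.odds_ratio
        d["or_ci_low"], d["or_ci_high"] = self.or_ci
        return d


def se_from_ci(point: float, ci_low: float, ci_high: float,
               is_ratio: bool = True, study: str = "") -> StudyEstimate:
    """Recover a study estimate from a point value and its 95% CI.

    Ratio-scale inputs (OR/RR) are transformed to logs first; the SE is the
    CI width divided by 2·1.959964.  A warning is emitted when the point
    estimate sits more than 2% away from the CI midpoint (geometric midpoint
    for ratios), which usually signals rounded or asymmetric inputs.
    """
    if not ci_low < ci_high:
        raise ValueError(f"need ci_low < ci_high, got ({ci_low}, {ci_high})")
    if is_ratio:
        if min(point, ci_low, ci_high) <= 0:
            raise ValueError("ratio-scale inputs must be positive")
        beta = math.log(point)
        lo, hi = math.log(ci_low), math.log(ci_high)
    else:
        beta, lo, hi = point, ci_low, ci_high
    se = (hi - lo) / (2.0 * Z_95)
    mid = 0.5 * (lo + hi)
    if abs(beta - mid) > 0.02 * max(abs(hi - lo), 1e-12) + 1e-12:
        logger.warning("se_from_ci%s: point %.4g is off the CI midpoint %.4g "
                       "(rounded inputs?)", f" [{study}]" if study else "",
                       beta, mid)
    return StudyEstimate(study=study, beta=beta, se=se)


def fixed_effect_meta(estimates: list[StudyEstimate]) -> MetaResult:
    """Fixed-effect inverse-variance-weighted combination.

    β = Σwᵢβᵢ/Σwᵢ with wᵢ = 1/seᵢ², se = 1/√Σwᵢ, two-sided normal P.
    Heterogeneity: Cochran Q = Σwᵢ(βᵢ − β)² on n−1 df and
    I² = max(0, (Q − df)/Q).
    """
    if not estimates:
        raise ValueError("no study estimates to combine")
    betas = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se ** 2 for e in estimates])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = beta / se
    p = max(float(2.0 * stats.norm.sf(abs(z))), np.nextafter(0, 1))
    q = float(np.sum(w * (betas - beta) ** 2))
    if q < 1e-12:  # single study or numerically homogeneous
        q = 0.0
    df = len(estimates) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return MetaResult(beta, se, beta - Z_95 * se, beta + Z_95 * se,
                      p, z, q, i2, len(estimates))
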