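"""Two-sample MR estimators on a harmonized variant set.

The causal effect of the exposure on the outcome is estimated by regressing
per-variant outcome effects on exposure effects:

* Wald ratio — the single-variant estimate β_y / β_x;
* IVW — inverse-variance-weighted regression through the origin, the primary
  estimate; a multiplicative random-effects variant inflates the SE by the
  residual dispersion when it exceeds 1;
* MR-Egger — the same regression with a free intercept; a non-zero intercept
  is evidence of directional horizontal pleiotropy (the intercept test);
* weighted median — the ratio at 50% of cumulative inverse-variance weight,
  consistent when up to half the weight comes from invalid instruments, with
  a parametric-bootstrap SE.

Effects can be rescaled from "per 1 unit of (log-scale) genetically predicted
expression" to "per f·100% relative reduction" via the factor ln(1/(1−f)),
with the sign flipped so positive numbers mean the effect of *lowering*
expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair, HarmonizedSet, orient_to_positive_exposure

Z_95 = 1.959964  # normal 97.5% quantile to the precision used for CI <-> SE


def _two_sided_p(z: float) -> float:
    return max(float(2.0 * stats.norm.sf(abs(z))), np.nextafter(0, 1))


@dataclass
class MREstimate:
    """One estimator's output: effect per unit exposure with normal-theory CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    model: str = "fixed"
    unit_note: str = "per 1 unit genetically predicted expression"

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, k: int,
                     model: str = "fixed", unit_note: str | None = None) -> "MREstimate":
        est = cls(method, beta, se, beta - Z_95 * se, beta + Z_95 * se,
                  _two_sided_p(beta / se) if se > 0 else np.nextafter(0, 1), k, model)
        if unit_note is not None:
            est.unit_note = unit_note
        return est

    @property
    def odds_ratio(self) -> float:
        """exp(beta); meaningful when beta is a log-odds ratio."""
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["odds_ratio"] = self.odds_ratio
        d["or_ci_low"], d["or_ci_high"] = self.or_ci
        return d


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-variant ratio estimate with the first-order delta-method SE."""
    if pair.beta_exposure == 0:
        raise ValueError(f"{pair.variant_id}: beta_exposure is zero, ratio undefined")
    beta = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    return MREstimate.from_beta_se("wald", beta, se, k=1)


def ivw(hset: HarmonizedSet, model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate (regression through the origin).

    Closed form: β = Σ wᵢ βxᵢ βyᵢ / Σ wᵢ βxᵢ² with wᵢ = 1/se_yᵢ².  Fixed
    model: se = 1/√(Σ wᵢ βxᵢ²).  Multiplicative random effects: the SE is
    scaled by the residual standard deviation when it exceeds 1 (never
    deflated below the fixed-effect SE).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = hset.k
    if k == 0:
        raise ValueError("IVW needs at least one variant")
    if k == 1:
        est = wald_ratio(hset.pairs[0])
        return replace(est, method="ivw", model=model)
    bx, _, by, sy = hset.arrays()
    w = 1.0 / sy ** 2
    denom = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by)) / denom
    se = 1.0 / math.sqrt(denom)
    if model == "multiplicative_random":
        resid_sd = math.sqrt(float(np.sum(w * (by - beta * bx) ** 2)) / (k - 1))
        se *= max(1.0, resid_sd)
    return MREstimate.from_beta_se("ivw", beta, se, k, model)


def egger(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Weighted least squares of β_y on β_x with intercept, weights 1/se_y².
    The set is oriented to positive exposure betas first (Egger is not
    invariant to per-variant sign conventions).  SEs use the usual WLS
    covariance scaled by max(1, residual variance); P-values are
    normal-theory.  The intercept P is the directional-pleiotropy test.
    """
    if hset.k < 3:
        raise ValueError("Egger requires >= 3 variants")
    oriented = orient_to_positive_exposure(hset)
    bx, _, by, sy = oriented.arrays()
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid ** 2)) / (hset.k - 2)
    cov = cov_unscaled * max(1.0, sigma2)
    intercept, slope = float(coef[0]), float(coef[1])
    se_i, se_s = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    return (
        MREstimate.from_beta_se("egger_slope", slope, se_s, hset.k,
                                model="multiplicative_random"),
        MREstimate.from_beta_se(
            "egger_intercept", intercept, se_i, hset.k,
            model="multiplicative_random",
            unit_note="average direct (pleiotropic) effect per variant"),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median: the value where cumulative normalized weight crosses ½.

    Step-CDF quantile; when the cumulative weight hits 0.5 exactly at a
    variant boundary the two bracketing values are interpolated (midpoint).
    A variant holding a strict majority of the weight is always returned.
    """
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w)
    j = int(np.searchsorted(cum, 0.5, side="left"))
    if j + 1 < len(v) and abs(cum[j] - 0.5) <= 1e-12:
        return float(0.5 * (v[j] + v[j + 1]))
    return float(v[j])


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimate with a parametric-bootstrap SE.

    Per-variant ratios are weighted by their first-order inverse variance
    (βx²/se_y²).  The SE resamples both studies' betas from normals centered
    at the observed values with the observed SEs, recomputing the statistic
    n_boot times; deterministic given the seed.
    """
    if hset.k < 3:
        raise ValueError("weighted median requires >= 3 variants")
    bx, sx, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise ValueError("zero exposure beta: ratio undefined")
    ratios = by / bx
    weights = bx ** 2 / sy ** 2  # 1 / Var(ratio), first-order delta method
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(by, sy)
        ok = bx_s != 0
        boot[b] = _weighted_median(by_s[ok] / bx_s[ok], bx_s[ok] ** 2 / sy[ok] ** 2)
    se = float(boot.std(ddof=1))
    return MREstimate.from_beta_se("weighted_median", beta, se, hset.k)


def rescale_to_relative_reduction(est: MREstimate, fraction: float) -> MREstimate:
    """Re-express an estimate per f·100% *relative reduction* in the exposure.

    A relative reduction by fraction f on a log-scale exposure is a shift of
    −ln(1−f); the per-reduction effect is therefore −β·ln(1/(1−f)).  SE and
    CI scale by the same factor; exponentiate ``odds_ratio`` for OR-scale
    outputs.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction {fraction} outside (0, 1)")
    scale = math.log(1.0 / (1.0 - fraction))
    beta = -est.beta * scale
    se = est.se * scale
    note = (f"per {fraction:.0%} relative reduction in genetically predicted "
            "expression (sign: positive = effect of lowering expression)")
    return replace(
        est, beta=beta, se=se,
        ci_low=beta - Z_95 * se, ci_high=beta + Z_95 * se,
        pvalue=est.pvalue, unit_note=note,
    )


def all_estimates(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0,
                  ivw_model: str = "fixed") -> dict[str, MREstimate]:
    """Run every estimator applicable to the set's size."""
    out: dict[str, MREstimate] = {"ivw": ivw(hset, ivw_model)}
    if hset.k >= 2:
        out["ivw_mre"] = ivw(hset, "multiplicative_random")
    if hset.k >= 3:
        slope, intercept = egger(hset)
        out["egger_slope"] = slope
        out["egger_intercept"] = intercept
        out["weighted_median"] = weighted_median(hset, n_boot=n_boot, seed=seed)
    return out
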