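"""MR-PRESSO: simulation-based horizontal-pleiotropy detection.

Three components: a *global test* comparing the observed weighted residual
sum of squares (RSS) of the IVW fit against a parametric null distribution; a
*per-variant outlier test* on each variant's RSS contribution (Bonferroni
adjusted); and, when outliers are removed, a *distortion test* asking whether
the resulting shift in the IVW estimate is larger than removing the same
number of random variants would produce.

Residuals are always taken against leave-one-out IVW fits so a strong
outlier cannot mask itself by dragging the fit toward its own point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate, ivw
from .harmonize import HarmonizedSet
from .io import logger


@dataclass
class PressoResult:
    global_rss_observed: float
    global_pvalue: float
    per_variant_pvalues: list[float]
    outlier_indices: list[int]
    estimate_before: MREstimate
    estimate_after: MREstimate | None
    distortion_pvalue: float | None
    n_sim: int
    seed: int

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items()
             if k not in ("estimate_before", "estimate_after")}
        d["estimate_before"] = self.estimate_before.to_dict()
        d["estimate_after"] = (None if self.estimate_after is None
                               else self.estimate_after.to_dict())
        return d


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, one per variant (vectorized via totals)."""
    num = np.sum(w * bx * by) - w * bx * by
    den = np.sum(w * bx ** 2) - w * bx ** 2
    return num / den


def _rss_contributions(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    beta_loo = _loo_ivw(bx, by, w)
    return w * (by - beta_loo * bx) ** 2


def presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Run the global, outlier and distortion tests on a harmonized set.

    The null distribution draws βx* ~ N(βx_i, se_x_i) and
    βy* ~ N(β̂₍₋ᵢ₎·βx_i, se_y_i) — the expected value of each variant's
    outcome effect under its leave-one-out fit — and recomputes the RSS with
    fresh leave-one-out fits on every simulated dataset.  Empirical P-values
    carry the +1 correction, so 1/(n_sim+1) is the attainable floor.
    Per-variant P-values are Bonferroni-multiplied by k and compared with
    ``outlier_alpha``.
    """
    k = hset.k
    if k < 4:
        raise ValueError("MR-PRESSO requires >= 4 variants")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    bx, sx, by, sy = hset.arrays()
    w = 1.0 / sy ** 2

    obs_contrib = _rss_contributions(bx, by, w)
    obs_rss = float(obs_contrib.sum())
    beta_loo = _loo_ivw(bx, by, w)

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, k))
    w_row = w[None, :]
    num = np.sum(w_row * bx_sim * by_sim, axis=1, keepdims=True) \
        - w_row * bx_sim * by_sim
    den = np.sum(w_row * bx_sim ** 2, axis=1, keepdims=True) \
        - w_row * bx_sim ** 2
    sim_contrib = w_row * (by_sim - (num / den) * bx_sim) ** 2
    sim_rss = sim_contrib.sum(axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (1 + n_sim))
    per_raw = (1 + np.sum(sim_contrib >= obs_contrib[None, :], axis=0)) / (1 + n_sim)
    per_adj = np.minimum(per_raw * k, 1.0)
    outliers = sorted(np.flatnonzero(per_adj < outlier_alpha).tolist())

    before = ivw(hset)
    after = None
    distortion_p = None
    if outliers:
        if len(outliers) == k:
            raise ValueError("all variants flagged as outliers; "
                             f"per-variant adjusted P: {per_adj.tolist()}")
        keep = [i for i in range(k) if i not in outliers]
        after = ivw(HarmonizedSet([hset.pairs[i] for i in keep]))
        d_obs = after.beta - before.beta
        d_rand = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(k, size=len(outliers), replace=False)
            mask = np.ones(k, bool)
            mask[drop] = False
            d_rand[s] = (np.sum(w[mask] * bx[mask] * by[mask])
                         / np.sum(w[mask] * bx[mask] ** 2)) - before.beta
        distortion_p = float((1 + np.sum(np.abs(d_rand) >= abs(d_obs)))
                             / (1 + n_sim))
        logger.info("presso: %d outlier(s) removed, IVW %.4f -> %.4f "
                    "(distortion P = %.3g)", len(outliers), before.beta,
                    after.beta, distortion_p)
    return PressoResult(obs_rss, global_p, per_adj.tolist(), outliers,
                        before, after, distortion_p, n_sim, seed)
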