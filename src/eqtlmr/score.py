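"""Individual-level weighted allele score and its phenotype associations.

Where a cohort's genotypes are available, each person's instrument value is
the weighted count of expression-increasing alleles: score_j = Σᵢ wᵢ·Gᵢⱼ with
dosages coded 0/1/2 and weights the per-allele expression effects.  The score
is then tested against quantitative traits (least squares) or binary outcomes
(logistic regression) with covariate adjustment — typically age, sex and 20
genetic principal components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimators import Z_95, MREstimate, rescale_to_relative_reduction
from .instrument import Instrument
from .io import logger


@dataclass
class ScoreResult:
    """Association of the allele score with one trait."""

    trait: str
    family: str
    beta: float        # per unit score; log-odds for logistic
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n: int
    covariates_used: list[str]

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.beta)) if self.family == "logistic" else None

    def to_dict(self) -> dict:
        d = vars(self).copy()
        if self.family == "logistic":
            d["odds_ratio"] = self.odds_ratio
            d["or_ci_low"] = float(np.exp(self.ci_low))
            d["or_ci_high"] = float(np.exp(self.ci_high))
        return d

    def as_estimate(self) -> MREstimate:
        return MREstimate("score", self.beta, self.se, self.ci_low,
                          self.ci_high, self.pvalue, k=0,
                          unit_note="per 1 unit of allele score")


def build_score(
    genotypes: pd.DataFrame | np.ndarray,
    instrument: Instrument,
    counted_alleles: dict[str, str] | None = None,
) -> np.ndarray:
    """Weighted allele score per sample: Σᵢ wᵢ·Gᵢⱼ.

    ``genotypes`` is samples × variants (DataFrame columns are variant IDs;
    a bare array must already be column-aligned with the instrument).  When
    ``counted_alleles`` maps variant IDs to the allele the dosage counts,
    variants counted on the non-effect allele are re-oriented (G → 2 − G,
    logged); weights are signed so positive weight always means the
    expression-increasing allele is counted.
    """
    if isinstance(genotypes, pd.DataFrame):
        missing = [v.variant_id for v in instrument.variants
                   if v.variant_id not in genotypes.columns]
        if missing:
            raise ValueError(f"instrument variants absent from genotypes: {missing}")
        g = genotypes[[v.variant_id for v in instrument.variants]].to_numpy(float)
    else:
        g = np.asarray(genotypes, float)
        if g.shape[1] != instrument.k:
            raise ValueError("genotype columns do not match instrument size")

    g = g.copy()
    for i, rec in enumerate(instrument.variants):
        counted = (counted_alleles or {}).get(rec.variant_id)
        if counted is None or counted == rec.effect_allele:
            continue
        if counted == rec.other_allele:
            g[:, i] = 2.0 - g[:, i]
            logger.info("build_score: %s re-oriented (dosage counts %s, "
                        "effect allele %s)", rec.variant_id, counted,
                        rec.effect_allele)
        else:
            raise ValueError(
                f"{rec.variant_id}: counted allele {counted} matches neither "
                f"{rec.effect_allele} nor {rec.other_allele}")
    return g @ np.asarray(instrument.weights, float)


def associate(
    score: np.ndarray,
    phenotype: pd.DataFrame,
    trait: str,
    family: str = "linear",
    covariates: list[str] | None = None,
) -> ScoreResult:
    """Regress a trait on the allele score with covariate adjustment.

    Linear: OLS.  Logistic: maximum-likelihood fit (Newton/IRLS as
    implemented by statsmodels, tolerance 1e-8, 100 iterations); complete
    separation is reported as an error rather than a spurious estimate.
    Missing data are handled by listwise deletion with the dropped count
    logged.
    """
    covariates = list(covariates or [])
    df = phenotype[[trait] + covariates].copy()
    df["_score"] = np.asarray(score, float)
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.info("associate: %d row(s) dropped (missing data)",
                    n_before - len(df))
    y = df[trait].to_numpy(float)
    X = sm.add_constant(df[["_score"] + covariates].to_numpy(float))

    if family == "linear":
        fit = sm.OLS(y, X).fit()
        beta, se = float(fit.params[1]), float(fit.bse[1])
        p = float(fit.pvalues[1]) if se > 0 else np.nextafter(0, 1)
        if se == 0:
            logger.warning("associate: exact fit for %s (se = 0), degenerate", trait)
    elif family == "logistic":
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        except Exception as exc:  # PerfectSeparationError and kin
            raise ValueError(
                f"logistic fit failed for {trait} ({exc}); if separation is "
                "present consider exact or penalized methods (not implemented)"
            ) from exc
        if not np.all(np.isfinite(fit.bse)) or abs(fit.params[1]) > 50:
            raise ValueError(
                f"apparent separation fitting {trait} (|coef| diverging); "
                "consider exact or penalized methods (not implemented)")
        beta, se = float(fit.params[1]), float(fit.bse[1])
        p = float(fit.pvalues[1])
    else:
        raise ValueError(f"unknown family {family!r}")
    return ScoreResult(trait, family, beta, se, beta - Z_95 * se,
                       beta + Z_95 * se, max(p, np.nextafter(0, 1)),
                       n=len(df), covariates_used=covariates)


def rescale_score_result(res: ScoreResult, score_sd_per_unit_expression: float,
                         fraction: float) -> MREstimate:
    """Convenience: re-express a score association per relative reduction.

    The score coefficient is per unit of allele score; dividing by the
    score's effect on expression (in practice ≈ 1 when weights are the
    expression betas) converts to per-unit-expression before rescaling.
    """
    est = res.as_estimate()
    est = MREstimate.from_beta_se(
        "score", est.beta / score_sd_per_unit_expression,
        est.se / score_sd_per_unit_expression, k=0)
    return rescale_to_relative_reduction(est, fraction)
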