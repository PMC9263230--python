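"""Synthetic cohorts with the statistical structure a cis-eQTL MR study assumes.

Two disjoint cohorts are simulated: an *exposure* cohort in which gene
expression is measured (emulating a blood eQTL consortium) and an *outcome*
cohort carrying the downstream traits (an LDL-like quantitative positive
control, null log-eGFR-like and log-ACR-like traits, and a liability-threshold
binary CKD-like outcome).  Per-variant marginal regressions on each cohort
yield the two-sample summary statistics the estimators consume.

Genotypes come from a Gaussian copula: a latent AR(1) normal vector with
adjacent correlation ``ld_decay`` is thresholded at the Hardy–Weinberg
genotype frequencies of each variant's minor-allele frequency.  This gives
tunable LD without haplotype reference panels; thresholding attenuates the
latent correlation, so the LD matrix handed to clumping is always the
empirical r² of the realized dosages, not the latent matrix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import SummaryStatRecord, LDMatrix, logger

# Per-purpose stream codes: each random stream is seeded with
# (scenario.seed, code) so cohorts and effect draws are independent yet
# reproducible.
_STREAM = {"effects": 0, "exposure": 1, "outcome": 2,
           "exposure_traits": 3, "outcome_traits": 4, "pleiotropy": 5}

COVARIATE_COLUMNS = ["age", "sex"] + [f"pc{i}" for i in range(1, 21)]


@dataclass
class SimScenario:
    """Study conditions for one simulated two-sample MR experiment.

    Defaults emulate the eQTL-instrument regime of a blood-expression MR
    study: 13 cis variants jointly explaining 1.5% of expression variance in
    an exposure cohort of 31,684, a binary outcome with 6% prevalence, and a
    modest positive causal effect of expression on the downstream traits.
    """

    n_exposure_cohort: int = 31_684
    n_outcome_cohort: int = 50_000
    n_variants: int = 13
    maf: np.ndarray | None = None          # default: evenly spaced 0.08–0.45
    ld_decay: float = 0.1                  # latent adjacent-variant correlation
    exposure_variance_explained: float = 0.015
    causal_effect: float = 0.2             # per unit expression, on outcome scale
    pleiotropy: str = "none"               # none | balanced | directional
    pleiotropy_magnitude: float = 0.0      # per-allele direct effect on outcome
    n_outliers: int = 0
    outlier_magnitude: float = 0.0
    liability_prevalence: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maf is None:
            self.maf = np.linspace(0.08, 0.45, self.n_variants)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.shape != (self.n_variants,):
            raise ValueError(
                f"maf length {self.maf.shape} != n_variants {self.n_variants}"
            )
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("maf values must be in (0, 0.5]")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must be in [0, 1)")
        if not 0 <= self.exposure_variance_explained < 1:
            raise ValueError("exposure_variance_explained must be in [0, 1)")
        if not 0 < self.liability_prevalence < 1:
            raise ValueError("liability_prevalence must be in (0, 1)")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")

    def variant_ids(self) -> list[str]:
        return [f"rs{9_000_000 + i}" for i in range(self.n_variants)]

    def rng(self, purpose: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[purpose]])


def simulate_genotypes(scenario: SimScenario, cohort: str) -> np.ndarray:
    """Simulate an (n × m) dosage matrix of 0/1/2 genotypes for one cohort.

    Marginals are Hardy–Weinberg at each variant's MAF; the latent Gaussian
    has corr(i, j) = ld_decay^|i−j|.  The counted (effect) allele is the
    minor allele.  Deterministic given (scenario.seed, cohort).
    """
    if cohort not in ("exposure", "outcome"):
        raise ValueError(f"cohort must be 'exposure' or 'outcome', got {cohort!r}")
    n = scenario.n_exposure_cohort if cohort == "exposure" else scenario.n_outcome_cohort
    m = scenario.n_variants
    rng = scenario.rng(cohort)
    rho = scenario.ld_decay
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if m > 1:
        innov = rng.standard_normal((n, m - 1)) * np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    p = scenario.maf
    # genotype classes 0/1/2 with probabilities (1-p)^2, 2p(1-p), p^2
    t0 = stats.norm.ppf((1.0 - p) ** 2)
    t1 = stats.norm.ppf(1.0 - p ** 2)
    return ((z > t0).astype(np.int8) + (z > t1)).astype(float)


def variant_effects(scenario: SimScenario) -> np.ndarray:
    """Per-allele effects of the variants on expression (unscaled shape).

    Magnitudes decay exponentially across the variant list with random signs;
    a single draw per scenario, shared by both cohorts.  The absolute scale
    is fixed later so the genetic component explains exactly the target
    fraction of expression variance in the cohort at hand.
    """
    rng = scenario.rng("effects")
    mags = 0.85 ** np.arange(scenario.n_variants)
    signs = rng.choice([-1.0, 1.0], size=scenario.n_variants)
    return mags * signs


def _pleiotropy_effects(scenario: SimScenario) -> np.ndarray:
    if scenario.pleiotropy == "none" or scenario.pleiotropy_magnitude == 0:
        return np.zeros(scenario.n_variants)
    rng = scenario.rng("pleiotropy")
    if scenario.pleiotropy == "directional":
        return np.full(scenario.n_variants, scenario.pleiotropy_magnitude)
    return rng.normal(0.0, scenario.pleiotropy_magnitude, scenario.n_variants)


def simulate_traits(
    genotypes: np.ndarray,
    scenario: SimScenario,
    cohort: str = "outcome",
    acr_detection_limit: float = 0.3,
) -> pd.DataFrame:
    """Build the phenotype table for one cohort's genotypes.

    expression  = G·b + ε, with b rescaled so the genetic component explains
                  ``exposure_variance_explained`` of the unit-variance trait;
    ldl         = causal_effect·expression + covariate effects + pleiotropy + ε
                  (the quantitative positive control);
    log_egfr    = age effect + ε (null trait, no expression effect);
    log_acr     = log of a lognormal trait left-censored at a detection limit
                  (values below the limit are substituted by the limit before
                  the log transform);
    ckd         = 1 when a latent liability (causal_effect·expression +
                  pleiotropy + ε) exceeds the quantile giving the target
                  prevalence.

    Covariates: age, sex and 20 principal-component-like columns.
    """
    n, m = genotypes.shape
    if m != scenario.n_variants:
        raise ValueError("genotype matrix does not match scenario.n_variants")
    rng = scenario.rng(f"{cohort}_traits")
    h2 = scenario.exposure_variance_explained

    b = variant_effects(scenario)
    g_centered = genotypes - genotypes.mean(axis=0)
    genetic = g_centered @ b
    sd_g = genetic.std()
    if h2 > 0 and sd_g > 0:
        b = b * np.sqrt(h2) / sd_g
        genetic = genetic * (np.sqrt(h2) / sd_g)
    else:
        b = np.zeros(m)
        genetic = np.zeros(n)
    expression = genetic + rng.normal(0.0, np.sqrt(1.0 - h2), n)

    age = rng.uniform(40.0, 70.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    pcs = rng.standard_normal((n, 20))
    alpha = _pleiotropy_effects(scenario)
    direct = g_centered @ alpha

    beta = scenario.causal_effect
    ldl = (beta * expression + direct + 0.01 * (age - 55.0) + 0.1 * sex
           + 0.05 * pcs[:, 0] + rng.normal(0.0, 1.0, n))

    log_egfr = -0.008 * (age - 55.0) + rng.normal(0.0, 0.2, n)

    acr = np.exp(rng.normal(0.0, 1.0, n))  # lognormal, no expression effect
    censored = acr < acr_detection_limit
    if censored.any():
        logger.debug("ACR: %.1f%% below detection limit, substituted",
                     100 * censored.mean())
    log_acr = np.log(np.where(censored, acr_detection_limit, acr))

    liability = beta * expression + direct + rng.normal(0.0, 1.0, n)
    thr = (liability.mean()
           + liability.std() * stats.norm.ppf(1.0 - scenario.liability_prevalence))
    ckd = (liability > thr).astype(int)

    table = pd.DataFrame(
        {"sample_id": [f"{cohort[:3]}{i:06d}" for i in range(n)],
         "expression": expression, "ldl": ldl, "log_egfr": log_egfr,
         "log_acr": log_acr, "ckd": ckd, "age": age, "sex": sex}
    )
    for i in range(20):
        table[f"pc{i + 1}"] = pcs[:, i]
    table.attrs["true_weights"] = b
    return table


# ---------------------------------------------------------------------------
# per-variant marginal regressions (the brute-force GWAS)
# ---------------------------------------------------------------------------

def compute_summary_stats(
    genotypes: np.ndarray,
    trait: np.ndarray,
    family: str = "linear",
    variant_ids: list[str] | None = None,
    scenario: SimScenario | None = None,
) -> list[SummaryStatRecord]:
    """Per-variant marginal regression of a trait on each dosage column.

    Linear family: single-variant OLS with intercept (closed form, vectorized
    across variants).  Logistic family: maximum-likelihood logistic regression
    per variant via statsmodels.  Effect allele is the counted (dosage)
    allele.  Monomorphic variants are emitted with beta/SE missing and a
    warning; an exact fit yields se = 0 and is flagged degenerate.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    n, m = g.shape
    if y.shape != (n,):
        raise ValueError("trait length does not match genotype rows")
    ids = variant_ids or (scenario.variant_ids() if scenario is not None
                          else [f"v{i:04d}" for i in range(m)])
    if scenario is not None:
        chroms = ["17"] * m
        poss = [40_000_000 + 1000 * i for i in range(m)]
        alleles = [("A", "G")] * m
    else:
        chroms, poss, alleles = ["17"] * m, list(range(1, m + 1)), [("A", "G")] * m

    eaf = g.mean(axis=0) / 2.0
    records: list[SummaryStatRecord] = []

    if family == "linear":
        gc = g - g.mean(axis=0)
        yc = y - y.mean()
        sxx = (gc ** 2).sum(axis=0)
        sxy = gc.T @ yc
        syy = float(yc @ yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx
            rss = np.maximum(syy - beta * sxy, 0.0)
            dof = max(n - 2, 1)
            se = np.sqrt(rss / dof / sxx)
        for j in range(m):
            if sxx[j] == 0:
                logger.warning("%s: monomorphic variant, no estimate", ids[j])
                records.append(SummaryStatRecord(ids[j], chroms[j], poss[j],
                                                 *alleles[j], eaf=float(eaf[j]),
                                                 beta=None, se=None, pvalue=None, n=n))
                continue
            if se[j] == 0:
                logger.warning("%s: exact fit (se = 0), degenerate", ids[j])
                p = None
            else:
                p = float(2.0 * stats.t.sf(abs(beta[j] / se[j]), n - 2))
                p = max(p, np.nextafter(0, 1))
            records.append(SummaryStatRecord(ids[j], chroms[j], poss[j],
                                             *alleles[j], eaf=float(eaf[j]),
                                             beta=float(beta[j]), se=float(se[j]),
                                             pvalue=p, n=n))
    elif family == "logistic":
        import statsmodels.api as sm

        for j in range(m):
            if g[:, j].std() == 0:
                logger.warning("%s: monomorphic variant, no estimate", ids[j])
                records.append(SummaryStatRecord(ids[j], chroms[j], poss[j],
                                                 *alleles[j], eaf=float(eaf[j]),
                                                 beta=None, se=None, pvalue=None, n=n))
                continue
            X = sm.add_constant(g[:, j])
            fit = sm.Logit(y, X).fit(disp=0)
            records.append(SummaryStatRecord(
                ids[j], chroms[j], poss[j], *alleles[j], eaf=float(eaf[j]),
                beta=float(fit.params[1]), se=float(fit.bse[1]),
                pvalue=max(float(fit.pvalues[1]), np.nextafter(0, 1)), n=n))
    else:
        raise ValueError(f"unknown family {family!r}")
    return records


def empirical_ld(genotypes: np.ndarray, variant_ids: list[str]) -> LDMatrix:
    """Empirical r² (squared Pearson correlation) of the dosage matrix."""
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(genotypes, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(list(variant_ids), r ** 2)


def inject_outliers(harmonized, count: int, magnitude: float, seed: int):
    """Add ``magnitude`` to the outcome beta of ``count`` random variants.

    Returns (modified copy, sorted list of perturbed indices).  A fixture for
    pleiotropy-outlier detection: the perturbed variants violate the
    exclusion-restriction assumption by construction.
    """
    import copy

    k = len(harmonized.pairs)
    if count >= k:
        raise ValueError(f"count {count} must be < number of variants {k}")
    out = copy.deepcopy(harmonized)
    if count == 0:
        return out, []
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(k, size=count, replace=False).tolist())
    for i in idx:
        out.pairs[i].beta_outcome += magnitude
    return out, idx


# ---------------------------------------------------------------------------
# end-to-end two-sample study
# ---------------------------------------------------------------------------

@dataclass
class TwoSampleStudy:
    """Everything one simulated two-sample MR experiment produces."""

    scenario: SimScenario
    exposure_stats: list[SummaryStatRecord]
    outcome_stats: dict[str, list[SummaryStatRecord]]
    ld: LDMatrix
    exposure_genotypes: np.ndarray
    outcome_genotypes: np.ndarray
    exposure_phenotypes: pd.DataFrame
    outcome_phenotypes: pd.DataFrame
    truth: dict


def simulate_two_sample(
    scenario: SimScenario,
    outcome_traits: tuple[str, ...] = ("ldl", "ckd"),
) -> TwoSampleStudy:
    """Run the full generator: two cohorts, traits, and summary statistics.

    Exposure-cohort statistics are per-variant effects on expression; outcome
    statistics are computed per requested trait (logistic for ``ckd``, linear
    otherwise) on the disjoint outcome cohort.
    """
    ids = scenario.variant_ids()
    g_exp = simulate_genotypes(scenario, "exposure")
    ph_exp = simulate_traits(g_exp, scenario, cohort="exposure")
    g_out = simulate_genotypes(scenario, "outcome")
    ph_out = simulate_traits(g_out, scenario, cohort="outcome")

    exposure_stats = compute_summary_stats(
        g_exp, ph_exp["expression"].to_numpy(), "linear", scenario=scenario)
    outcome_stats = {
        trait: compute_summary_stats(
            g_out, ph_out[trait].to_numpy(),
            "logistic" if trait == "ckd" else "linear", scenario=scenario)
        for trait in outcome_traits
    }
    truth = {
        "causal_effect": scenario.causal_effect,
        "true_weights": ph_exp.attrs["true_weights"].tolist(),
        "pleiotropy": scenario.pleiotropy,
        "pleiotropy_magnitude": scenario.pleiotropy_magnitude,
        "pleiotropy_effects": _pleiotropy_effects(scenario).tolist(),
        "seed": scenario.seed,
    }
    return TwoSampleStudy(scenario, exposure_stats, outcome_stats,
                          empirical_ld(g_exp, ids), g_exp, g_out,
                          ph_exp, ph_out, truth)


def simulate_summary_pair(scenario: SimScenario, trait: str = "ldl"):
    """Light-weight path: exposure and one linear outcome trait's statistics.

    Avoids the logistic fits and phenotype extras; used by replicated
    calibration studies where only the quantitative-outcome summary
    statistics are needed.
    """
    g_exp = simulate_genotypes(scenario, "exposure")
    ph_exp = simulate_traits(g_exp, scenario, cohort="exposure")
    g_out = simulate_genotypes(scenario, "outcome")
    ph_out = simulate_traits(g_out, scenario, cohort="outcome")
    exposure_stats = compute_summary_stats(
        g_exp, ph_exp["expression"].to_numpy(), "linear", scenario=scenario)
    outcome_stats = compute_summary_stats(
        g_out, ph_out[trait].to_numpy(), "linear", scenario=scenario)
    return exposure_stats, outcome_stats
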