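# Methods

## Model and assumptions

The package estimates the causal effect of a gene's expression level on
downstream traits using *cis* genetic variants as instrumental variables.
The identification assumptions are the usual MR triple: the instrument is
associated with expression (relevance, checked via r² and F), shares no
confounder with the outcome (guaranteed by random allele assortment), and
affects the outcome only through expression (exclusion restriction — the
assumption the sensitivity analyses interrogate).

In the two-sample setting only marginal summary statistics are used:
β̂ˣᵢ ± σˣᵢ from an expression (eQTL) study and β̂ʸᵢ ± σʸᵢ from a disease GWAS
in a non-overlapping population.  Under valid instruments each ratio
β̂ʸᵢ/β̂ˣᵢ estimates the same causal slope; IVW pools them by inverse outcome
variance.  MR-Egger relaxes exclusion to the InSIDE condition (direct
effects independent of instrument strength) and reads average directional
pleiotropy off its intercept.  The weighted median tolerates up to half the
weight on invalid instruments.  MR-PRESSO attacks the same violation
nonparametrically by simulating the null distribution of the weighted
leave-one-out residual sum of squares.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `cis_window_bp` | 500,000 | window around the gene body (1-based, inclusive; measured from gene start/end, not the TSS) |
| `p_threshold` | 0.05 | strict (<) P filter for expression association |
| `r2_threshold` | 0.01 | clumping cutoff on squared dosage correlation |
| `relative_reduction` | 0.34 | reporting unit; effects scaled by ln(1/(1−f)) ≈ 0.4155 |
| `eaf_tolerance` | 0.08 | palindromic variants with EAF in [0.42, 0.58] on either side are dropped |
| `n_boot` | 1,000 | weighted-median parametric bootstrap draws |
| `n_sim` | 1,000 | MR-PRESSO null simulations (P-value floor 1/(n_sim+1)) |

The relative-reduction convention treats the exposure as log-scale
expression, so a reduction by fraction f is a shift of −ln(1−f); estimates
are reported on both the per-unit and per-reduction scales so the convention
is auditable.  The strength statistic is the standard
F = (r²/k)/((1−r²)/(n−k−1)); at r² = 1.5%, n = 31,684, k = 13 it evaluates
to 37.1.  (A historically reported value of 32.9 for this configuration does
not satisfy this formula — possibly a per-variant mean F; the package
reports the standard formula only.)

## Synthetic data: what it emulates, and what it does not

`simulate` builds two disjoint cohorts (the two-sample structure is enforced
by independent random streams keyed on `(seed, cohort)`):

* **Genotypes** — a Gaussian copula: latent AR(1) normal with adjacent
  correlation `ld_decay`, thresholded at Hardy–Weinberg genotype
  frequencies.  This gives tunable LD without haplotype panels.
  Thresholding attenuates the latent correlation, so the LD matrix used for
  clumping is always the empirical dosage r², never the latent matrix.
* **Expression** — Σᵢ bᵢGᵢ + ε, with effect magnitudes decaying
  geometrically (ratio 0.85) and random signs, rescaled on the realized
  genotypes so the genetic component explains exactly the target variance
  (default 1.5% across 13 variants).  The decay shape is a modeling choice
  (no empirical effect-size distribution was available); it concentrates
  weight in a few strong eQTLs, as cis signals typically do.
* **Traits** — an LDL-like quantitative positive control
  (`causal_effect`·expression + small age/sex/PC effects + unit noise); a
  null log-eGFR-like trait; a log-ACR-like trait left-censored at a
  detection limit with substitution at the limit before the log transform;
  and a CKD-like binary outcome from a liability threshold at the quantile
  matching 6% prevalence.
* **Pleiotropy** — optional per-variant direct effects on the outcome
  bypassing expression: constant (directional) or zero-centred (balanced);
  `inject_outliers` additionally perturbs chosen outcome betas to create
  detectable exclusion-restriction violations.

Default cohort sizes are 31,684 (exposure, matching the blood eQTL study
scale) and 50,000 (outcome, a generic biobank scale).  The replicated
calibration studies use 20,000 per cohort, which keeps 200 replicates under
a minute while leaving per-variant instruments individually strong
(per-variant F ≈ 20–35).

What passing tests on these data do **not** show: robustness to haplotype-
level LD structure, allele-frequency mismatch between real consortia,
population stratification, sample overlap, or winner's-curse selection of
instruments — none of which the generator models.  The binary outcome is
generated on the liability (probit) scale but analysed by logistic
regression; the resulting scale mismatch (logit ≈ 1.6–1.8 × probit,
attenuated by the threshold model) is tolerated with widened bounds in the
binary-outcome tests.

## Numerical and design choices

* **Clumping determinism** — P-value ties break by larger |β|, then
  lexicographic variant ID, making output invariant to row order.
* **Harmonization** — join on variant ID; palindromic variants are resolved
  only when both EAFs are informative and concordant, otherwise dropped;
  missing EAF disables palindromic resolution (conservative).  The
  procedure is idempotent: harmonizing harmonized data changes nothing.
* **Egger orientation** — the set is internally flipped to positive
  exposure betas (Egger is not invariant to per-variant sign conventions);
  ratio-based estimators are unaffected by this flip.
* **Weighted median definition** — the step-CDF weighted quantile: sort
  ratios, accumulate normalized weights, return the ratio where the
  cumulative weight crosses ½, interpolating (midpoint) only when it hits ½
  exactly at a boundary.  This guarantees a variant carrying a strict
  majority of weight is returned exactly, a property smoother interpolation
  schemes lose.  Ratio weights use the first-order delta method
  (βx²/σy²); exposure uncertainty re-enters through the bootstrap.
* **SEs and P-values** — normal-theory throughout (no small-sample t
  corrections), matching common MR software; k is typically ~13, so Egger
  intercept tests run slightly anti-conservative, which the multiplicative
  max(1, σ̂) residual scaling offsets in practice (measured type-I error 5%
  at the default conditions).
* **IVW model** — fixed-effect is the headline for k ≤ 3, multiplicative
  random effects otherwise; both are always computed.  The random-effects
  SE is never allowed below the fixed-effect SE.
* **MR-PRESSO details** — residuals are against leave-one-out IVW fits;
  null draws take βx* from the observed exposure distribution and βy* from
  its leave-one-out prediction; empirical P-values carry the +1 correction;
  per-variant tests are Bonferroni-adjusted by k.  The distortion test
  compares the post-removal shift with removing the same number of random
  variants.
* **CI ↔ SE conversion** — uses 1.959964; published CIs rounded to two
  decimals limit recovery of combined P-values to ~±0.005, so worked-example
  agreement is asserted on OR and CI bounds (±0.01), not on P.
* **Degenerate inputs** — exact-fit regressions emit SE = 0 with a
  degeneracy warning (the record-level validator refuses to ingest SE ≤ 0,
  so such rows cannot silently re-enter a pipeline); monomorphic variants
  yield records with missing beta/SE; logistic separation raises an error
  recommending exact/penalized methods rather than returning a diverged fit.

## Known limitations

* Weak-instrument regression dilution attenuates all estimators toward the
  null; at the default conditions the measured relative bias is ≈4% for IVW
  and the weighted median and ≈7–9% for Egger (whose slope is the least
  precise).  Much smaller cohorts or variance-explained values push Egger
  past 10% attenuation.
* After removing a strong outlier, the IVW estimate moves in the direction
  of the true effect in ~95–96% of detections, but ends *strictly closer*
  to it in only ~87–89%: when the outlier lands on a low-weight variant its
  displacement is comparable to the estimator's sampling noise, so removal
  is sometimes a wash.  Both rates are reported by the reproduction script.
* No LD-aware estimation: clumping assumes the supplied r² matrix is the
  relevant LD; residual correlation below the threshold slightly
  underestimates IVW SEs.
* No proxy-variant lookup, no Steiger filtering, no multivariable MR, no
  random-effects meta-analysis (the meta model is fixed-effect by design).
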