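# Methods

## Model and procedure

`mrmediate` quantifies, from summary-level GWAS data alone, how much of an
exposure's causal effect on a binary outcome is transmitted through
candidate mediators. The design is two-sample (variant–exposure and
variant–outcome associations from non-overlapping cohorts) and two-step:

* **Total effect** `βT`: univariable IVW regression of outcome log-odds
  betas on exposure betas over the exposure's instruments (zero intercept,
  weights `1/se_out²`).
* **Step 1** `β₁` per mediator: the same IVW with the mediator's GWAS as
  the outcome, giving the exposure→mediator effect in mediator-SD units.
  Screened against a Bonferroni threshold `α/m` across the `m` candidate
  mediators, because several mediators are tested against the same
  exposure instruments.
* **Step 2** `β₂` per mediator: multivariable IVW of the outcome on the
  exposure *and one mediator at a time*, over the union of both traits'
  genome-wide-significant instruments. Each mediator is adjusted
  separately (pairwise with the exposure) rather than all jointly: the
  question answered per mediator is "the mediator's direct effect holding
  the exposure fixed", and pairwise fits avoid conditioning each lipid on
  collinear companions. Screened at nominal `α`.
* **Decomposition**: indirect effect `β₁β₂`, proportion mediated
  `β₁β₂/βT`. Every mediator's proportion uses the same total-effect
  denominator; proportions are reported ×100.

Standard errors for the composed quantities come from first-order Gaussian
error propagation (`propagate_se`): `se(a±b) = √(se_a²+se_b²)`,
`se(ab) = √(b²se_a² + a²se_b²)`,
`se(a/b) = |a/b|·√((se_a/a)² + (se_b/b)²)` with the `a = 0` limit handled as
`se_a/|b|`. Inputs are treated as independent. For the proportion this is
an approximation — indirect and total share the outcome sample — so the
result object carries an explicit `independence_assumed` flag rather than
hiding it. Proportions outside [0, 1] are reported as computed, with a
warning, never clipped.

All binary-outcome effects live on the log-odds scale; odds ratios are
exponentiated only at reporting time.

## Estimators

* **IVW** (`IVWEstimator`): closed-form weighted normal equations. The
  multiplicative random-effects variant (default) scales all SEs by
  `max(1, √(Q/dof))`, so it never undercuts the fixed-effects SE; whether a
  fixed- or random-effects model is appropriate is left to the analyst and
  both are exposed. One instrument reduces exactly to the Wald ratio
  `βy/βx` with SE `se_y/|βx|`. The same class fits the multivariable
  design (one column per exposure), with `Q` on `n − k` degrees of
  freedom. Exactly-zero exposure columns are treated as degenerate (zero
  coefficient, infinite SE) so the remaining exposures reduce to the
  smaller model; any other rank deficiency is an error.
* **MR-Egger** (`EggerEstimator`): weighted regression *with* intercept;
  the intercept is the directional-pleiotropy test. Exposure betas are
  oriented nonnegative first (flipping each SNP's sign pair), the usual
  identifiability convention. Inference uses the t distribution with
  `n − 2` df.
* **Weighted median**: per-SNP Wald ratios ordered, inverse-variance
  weights (second-order ratio variance `se_y²/βx² + βy²se_x²/βx⁴`)
  normalized; the estimate interpolates linearly where the cumulative
  weight crosses ½. SE by seeded parametric bootstrap (default 1000
  redraws of βx, βy from their sampling distributions).
* **Mode-based** (simple/weighted): normal-kernel density of the Wald
  ratios with bandwidth `factor × 0.9 · min(sd, MAD) · n^(−1/5)` (the
  MAD, scaled to be consistent for the normal, robustifies the Silverman
  rule); the estimate is the density argmax located on a 512-point grid
  and refined by bounded scalar optimization. SE by seeded bootstrap.
* **Battery**: the five methods above on one harmonized set, in fixed
  order, deterministic given one seed. They assume different pleiotropy
  models, so their agreement is evidence the IVW result is not an artifact
  of invalid instruments.

IVW/median/mode p-values are two-sided normal; Egger slope and intercept
use t with `n − 2` df. 95% CIs are `±1.96·se` (t quantiles for Egger).

## Instrument processing

Selection keeps `p < 5e-8` (strict inequality). Clumping is greedy on the
user-supplied LD matrix: repeatedly keep the smallest-p remaining SNP
(ties broken lexicographically by id, for determinism) and drop everything
with `r² ≥ 0.001` to it; no physical-distance window is used, since the LD
matrix is assumed to cover all candidate pairs. Instruments with
`F = (β/se)² < 10` are removed. Harmonization intersects on variant id,
flips outcome signs for swapped allele pairs, maps strand complements, and
keeps palindromic (A/T, C/G) variants only when both allele frequencies
are present, both outside `0.5 ± 0.08`, and concordant in direction — the
0.08 window is the common MR default; the procedure records an explicit
action (`kept`/`flipped`/`dropped_palindromic`/`dropped_incompatible`) for
every intersected variant so no exclusion is silent. p-values of exactly 0
(a truncation some GWAS exports produce) are clamped to the smallest
positive float with a logged warning.

## The synthetic-study generator

The generator exists so that every stage — file parsing through the final
mediation table — can be exercised against known truth. It draws
individual-level data from

```
X   = G·γ + c_x·U + ε_x                        (exposure)
M_k = α_k·X + G·δ_k + c_m·U + ε_k              (mediators)
Y   ~ Bernoulli(expit(b₀ + θ·X + Σ φ_k·M_k + c_y·U + G·π))
```

with independent binomial(2, maf) dosages, a shared standard-normal
confounder `U`, and disjoint cohorts per GWAS (plus a held-out LD sample),
then runs the same per-SNP regressions a GWAS would: closed-form simple
linear regression for quantitative traits and full maximum-likelihood
logistic regression (vectorised two-parameter Newton iterations) for the
binary outcome. A score-test statistic would be asymptotically equivalent;
the MLE is used because it avoids attenuating non-null per-SNP effects.

Genetic architecture mirrors real multi-trait settings: the first
`n_snps` variants affect the exposure (effects `γ ~ N(0, γ_sd²)`), and each
mediator owns a further disjoint block of `n_mediator_snps` variants
(`δ_k ~ N(0, δ_sd²)`). This separation matters twice over. First, the
mediator-specific variants reach the outcome only through the mediator, so
they are exactly the extra instruments multivariable MR needs to identify
`φ_k` separately from `θ` — with `δ = 0` the mediator column of the MVMR
design is `α_k` times the exposure column plus noise and the direct effect
is unidentified. Second, had `δ` been placed on the exposure's own
instruments it would act as massive heterogeneity in the step-1 regression
(each unit of `δ_sd` dwarfs the mediator-GWAS standard errors), destroying
the step-1 screen. `pleiotropy_sd` is a separate knob drawing direct
SNP→outcome effects `π` *on the exposure's instruments* — precisely the
violation the Egger intercept and the robust estimators are designed to
detect; 0 means all instruments are valid.

Residual variances are chosen so each quantitative trait has population
variance 1; traits are then empirically standardized (factors recorded),
so `θ`, `α`, `φ` are on the analysis scale and the ground truth follows
exactly from the configuration: `total = θ + Σ α_k φ_k`,
`indirect_k = α_k φ_k`, `proportion_k = indirect_k / total`. Because the
outcome model is logistic and log-odds are non-collapsible, these truths
are first-order approximations for large effects; the bundle records this
as a flag with a `truth_tolerance` of 0.04 on the proportion scale, which
parameter-recovery checks use as their band.

Defaults mirror a UK-Biobank-scale obesity/gallstone analysis at desk
size: 50 exposure instruments (γ_sd = 0.08 at n = 10⁵ gives median per-SNP
F ≈ 100, comfortably past both the 5e-8 and F > 10 screens), one mediator
with `α = 0.25`, `φ = 0.28`, `θ = 0.63` — total log-odds 0.70 (OR ≈ 2.0)
with 10% mediated — case fraction 0.0775, confounder loadings (0.3, 0.3,
0.2), cohorts of 2×10⁴ by default and 10⁵ in recovery experiments, and a
held-out LD sample of 2×10⁴ (large enough that sampling noise in r² stays
below the 0.001 clumping threshold). An optional block-AR(1) genotype mode
generates genuine LD to exercise clumping.

What the generator does **not** emulate: realistic LD from reference
panels (blocks are a caricature), sample overlap between cohorts,
assortative mating or population stratification, winner's-curse-free
instrument discovery in an external GWAS, and liability-scale outcome
models. Passing recovery tests therefore demonstrates correctness of the
estimators and plumbing under the stated structural model, not robustness
to every bias afflicting real two-sample MR.

## Numerical choices

* Clumping ties in p: lexicographic id order (determinism).
* IVW/MVMR covariance via `pinv` of the weighted normal equations;
  rank checks precede it.
* Weighted-median interpolation is linear between cumulative-weight
  brackets; bootstrap draws are vectorised and seeded (`n_boot = 1000`
  default).
* Mode argmax: 512-point grid bracketing followed by bounded
  minimization; degenerate zero-dispersion ratio sets return the weighted
  mean.
* All quantitative-trait GWAS p-values use t with `n − 2` df; binary use
  the Wald normal.
* Summary statistics are written with `%.17g` and read with round-trip
  float parsing, so write∘read is the identity on every float.
* Seeds: every stochastic component (bootstraps, the generator) takes an
  explicit seed; derived seeds come from `numpy.random.SeedSequence`.

## Problem sizes in the test suite

Unit tests run on studies of 2–5×10⁴ individuals per cohort with 40–60
SNPs, where the pipeline takes well under a second per study. The
parameter-recovery experiment uses 100 replicates at 10⁵ per cohort with
the default 50-instrument architecture; the acceptance script uses 30
replicates at the same size. These sizes were chosen so sampling error in
the proportion mediated (per-replicate sd ≈ 0.02) sits comfortably inside
the 0.04 recovery band while a full run stays in the minutes range on a
single core.

## Known limitations

* The proportion-mediated delta method ignores the indirect/total
  covariance (flagged in output); with shared outcome samples the true SE
  can differ modestly.
* Non-collapsibility of the odds ratio means log-odds "totals" and their
  decompositions are approximations; effects of the magnitude used here
  (OR ≈ 2) keep the error within a few percent.
* Correlated instruments are only supported through clumping (the IVW
  variance formula assumes independence); there is no
  generalized-least-squares IVW for correlated panels.
* No outlier-removal (e.g. leave-one-out or studentized-residual) or
  directionality (instrument-strength-ordering) filters; the sensitivity
  battery and bidirectional IVW checks are the provided defenses.
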