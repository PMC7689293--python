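# Methods

## The estimation problem

Two-sample MR treats genetic variants as instruments: if a variant
affects the outcome only through the exposure, the ratio of its outcome
and exposure associations estimates the causal effect.  The package's
focus is the mediation refinement of that design: a univariable estimate
gives the *total* effect of the exposure, and a multivariable model that
also conditions on a mediator's genetic effects gives the *direct*
effect.  For the smoking–adiposity–disease system this distinguishes
"smoking raises T2D risk" from "smoking raises BMI, and BMI raises T2D
risk".  Indirect effects are deliberately never reported for binary
outcomes: odds ratios are noncollapsible, so total-minus-direct is not an
estimand with a clean interpretation.

## Generating model (synthetic truth)

The synthetic generator encodes the causal diagram the analysis is meant
to recover:

    liability  = G γ_smk + c(age, sex, PCs) + ε,          ε ~ N(0, σ_L)
    smoking    = 1[liability > threshold(prevalence)]
    BMI (SD)   = θ_SB · smoking + G γ_bmi + c(·) + ε_B,   ε_B ~ N(0, σ_B)
    logit P(T2D) = α_T + θ_BT · BMI + θ_ST · smoking (+ G α_pleio)
    logit P(CAD) = α_C + θ_BC · BMI + θ_SC · smoking

Smoking initiation is a liability-threshold trait (so polygenic scores on
the liability scale exist); the disease outcomes are logistic, which
keeps the GWAS log-odds effects on the scale the estimators target.
σ_L and σ_B are set at truth-generation time so liability and BMI have
unit variance; α_T, α_C are solved numerically (Brent) so the expected
prevalence equals the target; the smoking threshold is the empirical
liability quantile.

**Genotypes.**  Dosages come from a latent AR(1) Gaussian copula: one
latent normal per individual and variant, correlated within blocks of 10
variants with latent ρ = √0.3 (so latent r² decays as 0.3^distance),
double-thresholded at the Hardy–Weinberg quantiles.  Marginals are exact
HWE at the drawn MAF (uniform 0.05–0.5); realized dosage LD sits slightly
below the latent target because of copula discretization.  The LD
reference distributed with a study reports the latent-truth r², which is
what clumping and LD scores consume.  Blocks are independent, 22
chromosomes, 5 kb spacing.

**Default parameters.**  Path coefficients are back-derived from the
instrument-scale effects reported for this trait system (per log-odds of
smoking liability, a marginal SNP effect passes through the smoking
prevalence variance p(1−p) ≈ 0.2475 at prevalence 0.45):

| parameter | default | derivation |
| --- | --- | --- |
| θ_SB | 0.93 SD | 0.16 SD per 2-fold smoking odds ÷ ln2 ÷ p(1−p) |
| θ_BT | 0.92 | log(2.5) per BMI SD |
| θ_ST | 0.34 | log(1.06) per doubling ÷ ln2 ÷ p(1−p) |
| θ_BC | 0.21 | log(1.23) per BMI SD |
| θ_SC | 0.66 | log(1.12) per doubling ÷ ln2 ÷ p(1−p) |
| prevalences | 0.45 / 0.20 / 0.20 | smoking ever / T2D / CAD (cohort-like) |

The mapping ignores the mild noncollapsibility attenuation of marginal
log-odds (roughly 0.85 here), so realized instrument-scale effects land
slightly below these inputs; recovery studies therefore score sign,
coverage and detection rather than point equality.

Per-trait genetics default to 150 causal variants with effects
N(0, 0.08²) (liability SD or BMI SD per allele).  This concentrates
heritability in few loci so that cohorts of n = 20 000 yield instruments
of realistic strength (F ≈ 90–120, tens of index variants) — the
desk-scale stand-in for consortium GWAS with n ~ 10⁶.  Directional
pleiotropy, when enabled, adds N(0.05, 0.02²) log-odds directly to the
outcome for the smoking-causal variants; 0.05 is roughly a third of a
typical instrument variant's mediated outcome effect, i.e. "substantial"
pleiotropy, and gives the intercept test ~90% power at k = 60 by design
calculation.

**What the generator does not emulate:** realistic human LD maps,
population stratification beyond nuisance PCs, assortative mating,
imputation error, allele-frequency differences between cohorts, and
selection/winner's-curse corrections.  Passing recovery tests show the
estimators work under the stated model, not that real-data estimates are
unbiased.

## GWAS scans

Continuous traits: exact per-variant OLS after residualizing genotype and
phenotype on age, sex and five PCs.  Binary traits: one-step score-based
logistic estimates from the covariate-only null fit (β̂ = U/V,
se = 1/√V with U the score and V the information of the residualized
genotype) — the standard large-cohort GWAS approximation, accurate for
the small per-variant effects the generator produces and vectorizable
over all variants.  Monomorphic variants are dropped.

## Numerical and design choices

- **Harmonization.**  Allele matching runs through direct match, strand
  complement, label swap and complemented swap; swaps negate the outcome
  beta and reflect its frequency.  Palindromic variants rely on
  frequencies alone: both must lie outside 0.5 ± 0.08 (window
  configurable, boundary inclusive via a 1e-9 epsilon), same side keeps,
  opposite sides flip.  Every row carries an action code so attrition is
  auditable.  Indels and multi-allelic rows are rejected at read time.
- **Clumping.**  Greedy by ascending p, ties broken by (chrom, pos) for
  determinism; the window is a radius (|Δpos| ≤ 250 kb default).  The
  joint instrument for MVMR re-clumps the union of per-trait instruments
  ranked by best p across traits, so overlapping LD is not double
  counted.
- **Random effects.**  IVW and MVMR use multiplicative residual-variance
  inflation floored at 1 (never below the fixed-effect SE); MR-Egger uses
  the same floor with t-based inference at k−2 df.  Egger rows are
  re-oriented to non-negative exposure betas first.
- **Weighted median.**  Midpoint-interpolation convention; SE from a
  seeded parametric bootstrap (default 5000 draws).  Note the midpoint
  convention is only *near*-invariant to duplicating every variant: the
  interpolation knots shift; the property test bounds the wiggle by the
  local ratio spacing.
- **MVMR degenerate designs.**  An exposure whose effects are all zero is
  dropped from the design (direct effect 0, SE undefined) so the nested
  single-exposure identity holds; genuinely collinear exposure columns
  raise an error naming the pair.  A simplified conditional-F diagnostic
  (weighted residual mean square of one exposure regressed on the others)
  is reported but never gated on.
- **Steiger.**  Observed-scale r² = z²/(z²+n) per variant for both binary
  and continuous traits (no liability-scale conversion); Fisher-z test at
  the median sample sizes; sensitivity over a 6×6 grid of reliability
  multipliers {0.5…1.0} per trait, reported as supporting/opposing grid
  volume (∞ when unanimous).
- **LDSC.**  One re-weighting iteration instead of full IRLS (adequate at
  synthetic scale); jackknife over 200 contiguous blocks (shrinking to
  n/25, minimum 20); rg clipped to [−1, 1]; non-positive h² flags rg
  undefined.  A constant LD-score regressor yields slope 0 by
  convention.  Because the re-weighting uses trait-specific provisional
  h², rg is only approximately invariant to rescaling one trait's
  z-scores.
- **2SPS.**  Binary predicted exposure is carried as the fitted
  probability (standard predictor substitution), SEs are model-based, and
  a stage-1 partial F < 10 aborts.  The mediator score uses the same
  variants with mediator-derived weights; when those weights are all zero
  the mediator channel is dropped and the model collapses onto the
  unadjusted one exactly.  Because both channels are built from the same
  variants they are strongly collinear; adjusted-model CIs are
  correspondingly wide, which is faithful to the design.
- **Determinism.**  All randomness flows through numpy Generators seeded
  from explicit arguments; replicate studies spawn 31-bit child seeds
  from a master seed.  Identical config + seed reproduces every output
  byte for byte.

## Validation studies and problem sizes

The replicate studies in `validation.py` (also run by
`scripts/acceptance.py`) use: 50 replicate two-sample studies at the
default truth with θ_ST = 0 (cohorts of 20 000, 5000 variants) for the
mediation decomposition; 100 replicates at 100 variants for
directionality (the continuous lifetime-smoking exposure, whose
instrument explains ≥5× more exposure than outcome variance; causal sets
are kept disjoint there, since in a 100-variant genome independent draws
would make a third of the instrument pleiotropic — a different scenario
than the directionality test targets); 500
summary-level replicates for Egger intercept size and power; 20+30
summary-level replicates for genetic-correlation recovery and null
calibration.  Unit tests exercise the same machinery at quarter scale
(400–2500 variants, cohorts of 4000–16 000) to stay fast; the scales
above are the package's reference conditions.

## Known limitations

No MR-PRESSO-style outlier pruning, mode-based or penalized estimators;
no proxy-variant lookup or liftover; no liability-scale heritability or
sample-overlap intercept modelling in LDSC; no bootstrap/sandwich SEs by
default in 2SPS (a seeded bootstrap is available); binary-exposure 2SPS
coefficients are on the predicted-probability scale, so their OR
conversion is a convention, not comparable across instruments of
different strength.
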