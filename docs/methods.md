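# Methods

## Model and scope

Two-sample summary-data MR treats L approximately independent SNPs as
instruments for an exposure.  For SNP j the exposure GWAS reports
(βe_j, σe_j) and the outcome GWAS (βo_j, σo_j), both on the log-odds scale
for binary traits.  Under the three instrumental-variable assumptions
(relevance, independence from confounders, exclusion), the structural model
is

    βo_j = θ·βe_j + r_j ,

with θ the causal effect and r_j a per-SNP direct (pleiotropic) effect,
zero for valid instruments.  The per-SNP Wald ratio β̂_j = βo_j/βe_j has
first-order delta-method SE σo_j/|βe_j|; second-order terms are omitted
(they matter only for weak instruments, which the F-filter removes).

## Instrument selection

The filter chain, in pipeline order: exposure p-value threshold (defaults
5×10⁻⁸ forward, 5×10⁻⁶ reverse — a conventional relaxation when few SNPs
reach genome-wide significance in a small GWAS); greedy LD clumping
(ascending p-value, ties broken by SNP id for determinism; an index SNP
removes same-chromosome SNPs within the window whose r² with it reaches the
ceiling; defaults r² < 0.001, 10,000 kb); weak-instrument filter with
per-SNP R² = 2·EAF·(1−EAF)·β² and F = R²(N−2)/(1−R²), dropping F < 10
(per-SNP rather than cumulative R², so the rule does not depend on the
instrument count); outcome-association filter p < 5×10⁻⁵ (flip-invariant,
so it may run before harmonization); harmonization; Steiger filter;
confounder exclusion list.  For binary traits N is cases + controls; no
effective-sample-size correction is applied.  SNPs without EAF have
undefined R²/F and are excluded (`no_eaf`) rather than imputed, since both
formulas require EAF.

LD information is always user-supplied (square r² matrix or long-format
pair table plus a position table); the package never queries a remote
reference panel, which keeps selection fully reproducible from inputs on
disk.

### Harmonization

Outcome records are aligned to the exposure's effect allele: matching
alleles pass through; swapped alleles negate βo and complement EAF;
strand-complemented representations are recoded first (missing EAF stays
missing under a flip).  Palindromic SNPs (A/T, C/G) are always removed —
no allele-frequency rescue — trading data retention for correctness, since
their strand cannot be resolved from alleles alone.  Every input SNP ends
up either as a harmonized pair or as one exclusion-log entry.

### Steiger directionality

A SNP that explains more variance in the outcome than in the exposure
likely acts in the reverse direction.  Per SNP, R² is computed on each side
from the printed formula; the SNP is kept only when R²_exp > R²_out and the
one-sided Fisher-z test of the correlations r = √R²,

    z = (atanh r_exp − atanh r_out) / √(1/(n_exp−3) + 1/(n_out−3)) ,

is significant at 0.05.  Equality gives z = 0, p = 0.5: not significantly
TRUE, so excluded.  A pooled-set variant (r = √ΣR² per side) is exposed via
`steiger_direction` for reporting; the filter itself is per-SNP.  SNPs
lacking EAF on either side pass with a warning, as their direction is
untestable.  The exact correlation construction (from EAF/β rather than
from p/n) is this package's documented choice; variants differ across
implementations.

## Estimators

* **IVW.**  Inverse-variance-weighted mean of the Wald ratios, weights
  w_j = 1/se_j².  Fixed-effect SE (Σw)^(−1/2); the default multiplicative
  random-effects variant inflates it by max(1, √(Q/(L−1))), a robust
  default when the heterogeneity level is unknown.  One instrument reduces
  to the Wald ratio (flagged).
* **MR-Egger.**  WLS of βo on βe with free intercept, weights 1/σo², after
  orienting all βe ≥ 0 (the intercept is orientation-dependent; a fixed
  convention makes results deterministic).  Slope = causal effect under
  InSIDE; intercept ≠ 0 indicates directional pleiotropy.  Both SEs carry
  the inflation floor max(1, √(RSS_w/(L−2))); p-values use t(L−2) (the
  regression convention), CIs are normal-theory ±1.96·se like every other
  estimator here.
* **Weighted median.**  The weighted 50th percentile of the ordered ratios
  (cumulative mid-weights, linear interpolation), consistent when valid
  instruments carry ≥ 50% of the weight.  SE is the SD of the statistic
  over n_boot = 1000 seeded parametric-bootstrap resamples
  β̂*_j ~ N(β̂_j, se_j); p from the normal approximation.  This bootstrap SE
  is mildly conservative: in the calibration study the null rejection rate
  at nominal 0.05 sits near 0.027, and coverage near 0.97.
* **cML-MA.**  For each candidate count K of invalid instruments, minimize
  Σ_j [(βo_j − θb_j − r_j)²/σo_j² + (βe_j − b_j)²/σe_j²] with at most K
  nonzero r_j.  Profiling b_j (and r_j on its support) reduces the problem
  to the exact profile deviance Σ_{j∉S} (βo_j − θβe_j)²/(σo_j² + θ²σe_j²);
  the fit alternates support selection (top-K squared standardized
  residuals, stable tie-break) with a 1-D Brent minimization of that
  deviance, from an IVW-fixed start, until support and θ stabilize
  (tol 10⁻⁸, max 100 iterations; non-converged K dropped with a warning).
  The within-support θ-step is numerical rather than a fixed-weight
  closed-form update because θ enters the profile variance; both solve the
  same constrained-ML objective.  BIC(K) = dev(θ̂_K) + K·log L; model
  averaging uses weights ∝ exp(−BIC/2); the averaged variance is
  Σw_K(se_K² + (θ̂_K − θ̄)²) with se_K from the numerical curvature of the
  profile deviance (Var ≈ 2/dev″).  As σe → 0 the K = 0 fit equals
  IVW-fixed exactly.  K defaults to 0…L−2; only BIC averaging is
  implemented (no data-perturbation variant), which also makes the
  estimator deterministic.

All estimators are invariant to pair reordering; negating both effect
columns leaves θ̂ unchanged while negating only the outcome negates it.

## Sensitivity battery

Cochran's Q over the ratios (df L−1) and Rücker's Q′ about the Egger fit
(df L−2), both against χ².  MR-PRESSO uses the leave-one-out weighted RSS
as observed statistic; n_sim = 1000 parametric replicates (defaults: outlier
significance 0.05, add-one empirical p so p is never exactly 0 — these are
artifact defaults, labelled as such in outputs) give the global p, per-SNP
outlier p (Bonferroni-corrected by L), and a distortion p comparing the
IVW shift after outlier removal against removal of equally many random
SNPs (two-sided empirical).  Radial MR defaults to first-order weights
w_j = βe_j²/σo_j², under which the per-SNP contributions sum *exactly* to
Cochran's Q (an identity used as a test); modified second-order weights are
available by flag.  Leave-one-out flags a SNP whose omission flips the sign
of the estimate or moves p across 0.05.  All of this is bit-reproducible
from (input, seed).

## Reporting

OR = exp(β) with CI exp(β ± 1.96·se).  The FDR family is the set of
outcomes within one analysis direction (not pooled across directions);
Benjamini–Hochberg step-up adjustment is applied to the IVW p-values — the
primary estimator — leaving other methods' p-values raw.  Significance
requires both raw and adjusted p < 0.05.  Output tables keep full
precision; printed summaries round to 3 decimals.

## Synthetic generator

`synthgwas` draws L independent instruments: EAF ~ U(0.05, 0.95); true
effects half-normal |N(0, 0.05)| — the effect allele is defined as the
exposure-increasing allele, which gives directional pleiotropy a
well-defined orientation matching the estimators' βe ≥ 0 convention —
resampled per SNP until the true-effect F-statistic clears a floor
(default 30, i.e. clearly strong instruments); observed effects add noise
with the standardized-trait approximation se ≈ 1/√(2·EAF(1−EAF)·N) (no
case-control imbalance correction — adequate for exercising estimator
math, not for matching any particular study's noise exactly).  Pleiotropy
regimes: none, balanced (mean-zero r_j), directional (r_j ~ N(mean, sd) on
an exact round(prop·L) subset), and an InSIDE-violating mode where r_j
tracks instrument strength.  Configurable fractions of SNPs are made
palindromic, strand-complemented or allele-swapped in the outcome file to
exercise harmonization.  Presets carry the case+control totals of six
large GWAS (exposure 130,644; outcomes 348,676 / 487,511 / 436,182 /
3,024 / 6,618) so noise regimes span realistic study sizes.  No LD between
instruments is simulated (the generator models the post-clumping world);
LD-clumping correctness is tested against an exhaustive oracle on small
user-specified LD tables instead.

What passing tests show — and don't: recovery, coverage and robustness
hold under the generator's Gaussian, independent-instrument, correctly-
specified-SE world.  Real GWAS pairs add sample overlap, LD misspecification,
allele-frequency mismatches between cohorts, and selection effects
(winner's curse) that the generator deliberately omits.

## Simulation-study sizes

The calibration harness uses L = 50 instruments, 500 replicates for bias
and coverage at θ ∈ {0, 0.1} and 1000 null replicates for type-I error;
the contamination study uses 30% invalid instruments with directional
pleiotropy N(0.03, 0.01) over 500 replicates; outlier detection plants a
10-SE displacement in one of 20 SNPs over 100 runs.  The acceptance script
reports the same quantities at moderately reduced replicate counts
(recorded per entry in its JSON output) as its standard problem sizes.

## Numerical choices and degenerate inputs

Missing values are "NA" (case-insensitive) or empty; only EAF may be
missing.  Floats serialize with shortest-round-trip repr, so file
round-trips are lossless.  p-values are clipped to (5·10⁻³²⁴, 1] when the
normal tail underflows.  Zero exposure effect makes the Wald ratio
undefined (error).  An all-equal exposure-effect design makes Egger
regression degenerate (error).  Pairs with fewer than 2 surviving
instruments are reported not-estimable rather than raising.  Clumping ties
(equal p) break by ascending SNP id; cML support ties break by stable sort
order.

## Known limitations

No proxy-SNP lookup for instruments missing in the outcome; no
allele-frequency-based palindrome rescue; no multi-allelic reconciliation;
no MR-RAPS/mode-based/multivariable estimators; no cML data-perturbation
variant; rendered plots are out of scope (the per-SNP radial and
leave-one-out tables are the plot-ready data).  The MR-Egger SE floor and
t-reference make its test slightly conservative at small L; the weighted
median's bootstrap SE is conservative as noted above.
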