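# Methods

## Setting and assumptions

`mrmediate` implements two-sample, two-step Mendelian randomization on
summary statistics. Three GWAS enter the analysis: a continuous exposure
X, a continuous mediator M and a binary outcome Y (log-OR scale). The
instrumental-variable assumptions are the usual three — each instrument is
associated with its trait, independent of confounders, and affects the
outcome only through the instrumented trait — plus the two-step structure
X → M → Y with a direct X → Y path. Effects combine on the log-OR scale:
the mediated effect is the product a·b of the exposure→mediator and
mediator→outcome effects, the direct effect is c − a·b, and the proportion
mediated is a·b/c. The decomposition is exact by construction (direct and
proportion are derived, never re-estimated), so the identities
mediated + direct = total and proportion·total = mediated hold to machine
precision on every invocation.

## Instrument QC

* **Selection**: strict p < 5×10⁻⁸ by default; a per-trait override (1×10⁻⁵)
  exists for traits with few genome-wide hits. An empty selection is a hard
  error that names the relaxed threshold.
* **Clumping**: greedy — visit SNPs by ascending p (ties broken by lexical
  SNP id, making the result order-invariant), accept a SNP unless it has
  r² ≥ 0.001 with an accepted SNP within 10 Mb on the same chromosome. The
  LD matrix is a required input (synthetic or user-supplied); SNPs absent
  from it are treated as independent and logged. The 10 Mb window is the
  conventional clumping window; only the r² cutoff is dictated by the
  analysis design.
* **Instrument strength**: per-SNP F ≈ (β/se)², identical to
  (n−2)R²/(1−R²) with R² = t²/(t²+n−2); F ≤ 10 instruments are removed as
  a hard filter so the "no weak instruments" guarantee is enforceable. An
  exact R²-based F using allele frequency and n is available when those
  fields are present (it assumes trait-SD units).
* **Steiger direction filter**: per SNP, variance explained in each trait
  is r² = t²/(t²+n−2); a SNP is kept when r²_exposure > r²_outcome and the
  Fisher-z two-sided test on the transformed correlations is significant at
  α = 0.05 (or the outcome signal is exactly zero). At biobank sample sizes
  every genuine instrument passes; reverse-causal SNPs with several-fold
  larger outcome r² are removed essentially always.

## Harmonization

Outcome effects are aligned to the exposure's effect allele: identical
pairs kept, swapped pairs sign-flipped, strand flips resolved by
complementing, palindromic (A/T, C/G) SNPs deleted unconditionally —
their strand cannot be resolved from allele labels, and deleting rather
than frequency-resolving them is this pipeline's policy (the
`palindrome_policy` enum has the single value `drop`, left extensible).
Pairs irreconcilable after complementing are dropped with a warning rather
than guessed at. Harmonization is idempotent, and joint sign flips leave
every downstream estimate invariant (tested).

## Estimators

* **Wald ratio** (1 SNP): β̂ᵧ/β̂ₓ with the first-order delta SE σᵧ/|β̂ₓ|;
  adequate for t = β̂ₓ/σₓ ≳ 10, where the second-order term contributes
  < 5%.
* **IVW** (≥ 2 SNPs): inverse-variance pooling of Wald ratios, weights
  β̂ₓ²/σᵧ²; algebraically the zero-intercept weighted regression of β̂ᵧ on
  β̂ₓ. The default standard error is multiplicative random-effects,
  inflating by √max(1, Q/(J−1)); fixed-effects is available by flag. The
  default follows the convention of standard two-sample MR tooling; the
  choice does not move the point estimate.
* **MR-Egger** (≥ 3 SNPs): the same regression with a free intercept after
  orienting all exposure effects non-negative. Slope and intercept SEs use
  √max(1, Q′/(J−2)) scaling and t inference on J−2 df. The intercept is the
  pleiotropy diagnostic; forcing it to zero reproduces fixed-effects IVW
  exactly.
* **Weighted median** (≥ 3 SNPs): order the per-SNP ratios, form cumulative
  midpoint weights (cumulative weight minus half the SNP's own weight,
  normalized), and interpolate linearly at 1/2. The SE is a seeded
  parametric bootstrap (default 1000 resamples of both effect vectors from
  their Gaussians). Note that with the midpoint-interpolation convention a
  SNP carrying just over half the weight pins the estimate only when its
  flanking cumulative weights balance; the step-function median would
  always return that SNP's ratio. We follow the interpolation convention
  used in the published estimator.
* p-values are two-sided Gaussian (t with J−2 df for Egger); the 95% CI
  multiplier is 1.959964 throughout; ORs are exponentiated log-ORs.

## Sensitivity diagnostics

Cochran's Q for IVW is computed on the ratio scale (weights 1/se(θ̂ⱼ)²,
J−1 df) and equals the weighted RSS of the zero-intercept regression;
the Egger heterogeneity statistic is Rücker's Q′ on the regression scale
(J−2 df). MR-PRESSO computes the observed weighted RSS against
leave-one-out IVW slopes, simulates n_sim (default 1000, the published
default) datasets from Gaussians centred on the leave-one-out fits, and
reports the global p as the exceedance fraction; per-SNP outlier p-values
are Bonferroni-adjusted over SNPs and flagged at α = 0.05; when outliers
are flagged, the distortion p compares the slope shift from removing them
with the shift from removing random subsets of equal size. All simulation
results are bit-reproducible given (seed, n_sim).

## The synthetic generator

`SimulationConfig` defaults *are* the study conditions: 45 exposure
instruments and 50 mediator instruments with per-SNP variance explained
0.1% (drawn Normal so that E[2p(1−p)γ²] = h²), MAF uniform on [0.05, 0.5],
cohort sizes 496,946 (exposure), 194,453 (mediator) and 332,020 with
6,303 cases (outcome), a = 0.06, b = ln 1.25, c′ = 0.22 — a true
proportion mediated of 5.74%. Summary statistics are generated directly at
the summary level: observed betas are true means plus Gaussian noise with
analytic SEs 1/√(2p(1−p)n), inflated on the outcome by the case-control
imbalance factor 1/√(φ(1−φ)). This is what two-sample MR consumes, and it
keeps a full study in milliseconds; it deliberately does not model
individual-level genotypes, population stratification or sample overlap.

Mediator-primary SNPs are part of the design: the mediator→outcome MR step
needs the mediator's own instruments, which reach the outcome only through
b·δ. Exposure-primary SNPs reach the mediator as a·γ and the outcome as
(a·b + c′)·γ. Optional features: balanced or directional pleiotropy
(directional offsets are applied in the orientation of the
exposure-increasing allele, since allele coding is arbitrary and a fixed
offset would otherwise cancel under Egger's orientation); outlier SNPs
with ±k·se_Y outcome offsets; reverse-causal SNPs whose primary outcome
effect is sized to a configurable multiple (default 5×) of an instrument's
Steiger r², with an induced exposure association the size of a genuine
instrument, so only direction filtering can catch them; palindromic allele
pairs at a configurable fraction; and constant-loading LD blocks whose
members share the tag's effect scaled by r = √r² and correlated sampling
noise (a one-factor simplification; member–member r² is the square of the
tag loading).

All randomness flows from one mandatory seed through a single generator;
repeat calls are byte-identical.

## Evaluation design and measured behaviour

The test suite checks, under the default conditions: IVW type-I error at
the nominal 5% (multiplicative random effects is mildly conservative,
~0.046–0.048 over 1000 seeds, within the 0.05 ± 0.02 band); Cochran's Q
mean within 5% of its df; Egger-intercept recovery of an injected 0.01
directional offset; ≥ 95% MR-PRESSO detection of a 10·se outlier at
n_sim = 1000; ≥ 90% Steiger removal of reverse-causal SNPs at n = 100k;
and full-pipeline recovery of the proportion mediated for true values
π ∈ {0.05, 0.25, 0.50} over 200 seeds each.

Two evaluation choices in the recovery experiment deserve note. First, π
is varied through the mediator→outcome effect b at fixed a = 0.06 and
fixed total effect: raising a instead pushes exposure-primary SNPs past
genome-wide significance *in the mediator GWAS*, contaminating the
mediator's instrument set with SNPs that also carry the direct X→Y path —
a genuine two-step-MR failure mode (it inflates b̂ by ~18% at a ≈ 0.5)
that is a property of instrument contamination, not of the mediation
arithmetic under test. Second, the decomposition is computed for every
seed rather than only for seeds where the mediator survives screening;
conditioning on a significant b̂ selects upward-fluctuating estimates and
biases recovery. The remaining small upward bias (~+5% relative) is the
E[1/ĉ] ratio bias of the proportion estimator, partly offset by
winner's-curse attenuation of the component estimates; it sits within two
Monte-Carlo standard errors at 200 seeds.

Problem sizes used by `scripts/acceptance.py` (500 null seeds, 50–100
seeds for the recovery and detection experiments) were chosen so every
quantity's Monte-Carlo error is small against the property being checked
while the whole script completes in well under a minute.

## Degenerate inputs and numerical choices

β̂ₓ = 0 SNPs are excluded from multi-SNP estimators with a warning (the
Wald ratio is undefined); a zero total effect makes the proportion
mediated missing, not infinite; a two-SNP Egger intercept is the exact
line's intercept reported with a df = 0 warning and no inference;
p-values are floored at 10⁻³²⁰ to avoid Gaussian-tail underflow; TSV
serialization uses shortest-round-trip float repr, so write→read→write is
byte-identical. Reports serialize with sorted keys, making pipeline runs
byte-reproducible at fixed seed.

## Known limitations

The generator's analytic-SE summary-level sampling means tests validate
estimator and pipeline behaviour, not robustness to individual-level
artefacts (relatedness, stratification, overlapping samples, INDELs,
imputation quality). LD blocks are one-factor; real LD is richer.
Mediation uses a single mediator and the difference method for the direct
effect; multivariable MR, interaction terms and simultaneous mediators are
out of scope. Published real-data quantities that depend on the private
instrument sets of the source GWAS (instrument counts, F ranges, Q values,
PRESSO p) cannot be reproduced at desk scale and are covered instead by
the property-based checks above.
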