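# Methods

## Model

Two-sample MR treats each genetic variant *j* as an instrument for the
exposure: with per-allele associations β̂x,j (exposure) and β̂y,j (outcome)
estimated in non-overlapping cohorts, the per-variant Wald ratio
β̂y,j / β̂x,j estimates the causal effect θ under the instrumental-variable
assumptions (relevance, independence from confounders, and no effect on the
outcome except through the exposure). For a binary outcome modelled by
logistic regression, β and θ are log odds ratios; reports exponentiate to
the OR scale.

The estimators combine the ratios in ways that trade efficiency against
robustness to horizontal pleiotropy:

- **IVW**: zero-intercept weighted regression of β̂y on β̂x with weights
  1/se²y — efficient, but biased by any directional pleiotropy. The
  multiplicative random-effects variant (the default whenever k ≥ 2)
  inflates the SE by √max(1, Q/(k−1)) to absorb heterogeneity; the fixed
  variant is available by flag. Which variant a study labels "IVW" varies
  by convention, so the pipeline reports both.
- **MR-Egger**: the same regression with a free intercept. Under InSIDE
  (pleiotropic effects independent of instrument strength) the intercept
  estimates the mean pleiotropic effect and the slope remains consistent
  for θ. Pairs are reflected to β̂x ≥ 0 before fitting, the conventional
  orientation without which the fit is not invariant to per-SNP allele
  recoding. Inference uses t with k−2 df and a multiplicative
  overdispersion scale floored at 1.
- **Weighted median**: the 50% point of the inverse-variance-weighted,
  sorted ratio distribution (ratio variance se²y/β̂²x), interpolated
  linearly; consistent when valid instruments carry ≥ 50% of the weight.
- **Simple/weighted mode**: the argmax of a normal-kernel density of the
  ratios on a 512-point grid spanning [min − 3h, max + 3h], with a
  modified Silverman bandwidth h = 0.9·min(sd, IQR/1.349)·k^(−1/5) times a
  user bandwidth factor; the weighted variant weights each kernel by the
  ratio's inverse variance. Degenerate spread (h = 0) returns the common
  ratio. Median and mode SEs come from a seeded parametric bootstrap
  (β̂x, β̂y resampled from normals at their SEs; default 1000 draws).

95% intervals use the normal quantile 1.959964 throughout except MR-Egger's
t quantile; the Wald-ratio SE is the first-order delta approximation
se_y/|β̂x| (the second-order term is omitted and matters only for weak
instruments that the F screen removes).

## Diagnostics

Cochran's Q over the ratios (weights β̂²x/se²y) is referred to χ²(k−1).
MR-PRESSO computes, for each SNP, the residual from the IVW fit that
excludes it; the weighted residual sum of squares is compared against a
Monte-Carlo null built by re-simulating β̂x and β̂y around the fitted values
at the observed SEs (weighted residuals match the weighted fit of the
original procedure). Per-SNP outlier p-values are Bonferroni-corrected over
k; the distortion test compares the observed all-SNP versus outlier-free
IVW shift against its simulated distribution. All Monte-Carlo p-values use
(1+b)/(1+n) so p = 0 cannot occur; a fixed seed makes the result bitwise
reproducible. Leave-one-out re-estimates IVW k times; funnel data pair each
ratio with its precision |β̂x|/se_y.

## Instrument selection

Variants pass at *P* < 1×10⁻⁵ — the relaxed threshold used when few
genome-wide-significant instruments exist for molecular traits — then greedy
clumping keeps the most significant variant of each correlated group
(r² ≥ 0.001 within 10,000 kb; p-value ties broken by identifier for
determinism). LD is supplied as an explicit labelled r² matrix rather than
computed from a reference panel, so the package has no external binary
dependency; variants absent from the matrix are treated as independent with
a warning, and the distance test is skipped when positions are missing.
Per-SNP strength uses R² = 2·EAF·(1−EAF)·β² and F = R²(N−K−1)/(K(1−R²));
the F > 10 screen is applied per SNP (K = 1), with the aggregate-K statistic
also exposed. Rows lacking a usable EAF stay in the analysis but are
excluded from R²/F bookkeeping, since the estimators do not need allele
frequencies.

## Harmonization

Matching is by variant identifier (positions are advisory). Outcome alleles
equal to the exposure's are kept as-is; swapped alleles negate the outcome
effect; otherwise the outcome pair is strand-complemented and re-matched;
anything else is dropped as a mismatch. Palindromic SNPs are always dropped
— no frequency-based rescue is attempted, because inferring strand from
allele frequency is fragile exactly in the EAF range where palindromic SNPs
are common. Duplicated identifiers keep their first occurrence.

## Two-step mediation

The screen mirrors an exposure → mediator → outcome decomposition:
exposures must show a forward IVW effect (p < α = 0.05) and no reverse
effect (outcome→exposure p ≥ α); mediators must affect the outcome (p < α)
and show no pleiotropy evidence, operationalized as Egger intercept p < α
or MR-PRESSO global p < α; surviving pairs need an exposure→mediator effect
(p < α). The mediated effect is β₁×β₂ and the mediated proportion
(β₁×β₂)/β. Proportions outside [0, 100]% (suppression, where the product
opposes the total effect) are reported verbatim with a direction flag, never
truncated. No CI is attached to the proportion by default; a delta-method SE
for the product, √(β₁²se₂² + β₂²se₁²), is available. Mediator instruments
come from the mediator GWAS alone (univariable two-step MR, not
multivariable MR), so correlated mediators are not mutually adjusted — a
documented limitation. Screening uses raw p-values by default (no
multiple-testing correction across traits); Bonferroni/FDR options exist.

## Synthetic data

The generator simulates summary statistics directly — two-sample MR consumes
nothing else — with se = 1/√(2·EAF(1−EAF)·N) for a standardized trait and
independent exposure/outcome noise (non-overlapping cohorts). Binary
outcomes use the effective sample size 4/(1/cases + 1/controls). Default
cohort sizes emulate a cytokine GWAS (N = 14,824), a metabolite GWAS
(N = 8,299) and a binary disease outcome (3,880 cases / 381,977 controls,
effective N ≈ 15,368).

Per-SNP true exposure effects are uniform on [0.03, 0.25] SD per allele — a
protein/metabolite-QTL-like architecture spanning F ≈ 4–470 at the default
sizes so that the F > 10 screen is exercised. The lower bound keeps
instruments from degenerating (near-zero β̂x makes ratios explode); the
spread is deliberately wide because MR-Egger's slope is attenuated by
regression dilution by the factor Var(γ)/(Var(γ) + se²x), and a narrow
effect distribution would make the attenuation, not pleiotropy, the
dominant error. Effects are positive so directional pleiotropy keeps a
coherent sign under the β̂x ≥ 0 orientation.

Scenario structure: a configurable fraction of SNPs receives a pleiotropic
outcome effect (constant for directional, zero-mean normal for balanced),
assigned independently of instrument strength, so InSIDE holds by
construction; a configurable fraction receives palindromic alleles; optional
LD blocks replicate the lead SNP's effect scaled by √r² and emit a
block-diagonal r² matrix; the outcome carries its own instrument set, which
affects the exposure only through an optional reverse-causation coefficient,
making bidirectional analyses meaningful. Mediation triples compose
effects: exposure SNPs act on the mediator with θ₁γ and on the outcome with
(direct + θ₁θ₂)γ; mediator SNPs act on the outcome with θ₂γm.

What the generator does **not** emulate: realistic LD from reference panels,
winner's curse in the discovery GWAS, sample overlap between cohorts,
population stratification, or allele-frequency differences between studies.
Tests passing on these simulations therefore certify the statistical
machinery under the stated model, not robustness to those real-data
artifacts.

One cross-trait subtlety the simulations do expose: at large mediator sample
sizes, an exposure's mediated associations (θ₁γ) can themselves cross the
relaxed instrument threshold in the mediator GWAS, contaminating the
mediator's instrument set with SNPs whose ratio estimates the total — not
the mediator's — effect; the pleiotropy gate then (correctly) excludes the
mediator. The chain-recovery checks therefore run at the default cohort
sizes above, where molecular-trait GWAS are small enough that this leakage
does not occur; avoiding it in general requires directionality filtering
(e.g. Steiger), which is out of scope.

## Problem sizes and numerical choices

Recovery and calibration checks use 100-SNP panels: 200 replicates for
estimator means (θ = 0.3, N = 50,000), 500 for IVW/Q type-I error, 200 for
MR-PRESSO calibration (30 SNPs, 500 Monte-Carlo draws), 100 for outlier
detection (30 SNPs + one 10·SE outlier, 1000 draws) and 100 for the
mediation chain — sizes at which Monte-Carlo noise on a rejection rate is
about ±1–2 percentage points. Bootstrap SEs in replicate loops that only
consume point estimates use a nominal draw count. Monte-Carlo p-values are
never zero by construction; the mode grid is deterministic given the data;
clumping ties break lexicographically; and every stochastic routine takes an
explicit seed (the CLI defaults to 20240401).
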