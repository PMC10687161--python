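# Methods

This note records the statistical model, the conventions and numerical choices
behind each stage, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the published description of this study
design is silent.

## Study design

The pipeline implements a two-step drug-target MR mediation analysis. Genetic
variants in a ±100-kb window around a drug-target gene, genome-wide
significantly associated (p < 5×10⁻⁸, strict inequality) with a downstream
lipid trait, proxy pharmacological modulation of the target. Instruments may be
in weak mutual LD (r² < 0.30) to maximize strength at a single locus; exposures
with genome-wide instruments (metabolites, proteins) use conventional strict
clumping (r² < 0.001). Both use a 10,000-kb clumping window interpreted as a
same-chromosome distance cap between the index variant and any variant it
discards. Instrument strength is assessed per variant as F = (β/se)², the
square of the marginal z-statistic, with F > 10 required; the per-variant
reading is the conservative one, and the filter runs after clumping (pruning
then strength-checking, the usual order of operations; the reverse order would
only change which member of an LD clump survives).

Greedy clumping sorts by p-value ascending with ties broken by variant id
(lexicographic) so that the retained set is a deterministic function of the
input *set*, not its order; idempotence and order-invariance are property-
tested.

## Harmonization

Summary files are joined on variant id only (no positional fallback — joins
must be deterministic). Non-palindromic variants are aligned by allele labels,
trying strand complementation before declaring a mismatch; swapped alleles
negate the outcome beta and reflect its allele frequency. Palindromic variants
(A/T, C/G) carry no strand information in their labels, so they are aligned by
allele frequency alone: both frequencies must be informative
(min(eaf, 1−eaf) < 0.42, the convention of the widely used R implementation of
this analysis family) and fall on the same side of 0.5, in which case the
reported orientation is accepted unchanged; anything else — including a missing
frequency — is dropped with an explicit status. Dropped pairs carry no betas
and can never reach an estimator.

## Estimators

All five estimators operate on per-variant ratio estimates β̂Yj/β̂Xj with
inverse-variance weights wj = β̂Xj²/σYj² (the first-order approximation that
ignores exposure-side noise, standard for strong instruments).

* **Wald ratio** (k = 1): β̂Y/β̂X with first-order delta-method se σY/|β̂X|;
  no second-order term.
* **IVW** (k ≥ 2): weighted regression through the origin. The fixed-effect
  se (Σwj)^(−1/2) is inflated by max(1, √(Q/(k−1))) — multiplicative random
  effects with the scale floored at 1 — and p-values are normal.
* **MR-Egger** (k ≥ 3): WLS of β̂Y on β̂X with intercept after orienting all
  β̂X ≥ 0 (negating both members of a pair, to which all estimators are
  invariant). Coefficient ses scale by max(1, σ̂) with σ̂² the weighted residual
  variance on k−2 df; both coefficients use t(k−2) p-values. The intercept is
  the average directional-pleiotropy estimate and doubles as the pleiotropy
  test.
* **Weighted median** (k ≥ 3): sort ratios, form cumulative weight midpoints
  sⱼ = Σᵢ≤ⱼ wᵢ′ − wⱼ′/2 with normalized weights, and interpolate linearly at
  s = 0.5.
* **Simple/weighted mode** (k ≥ 3): argmax over a fixed 512-point grid
  (spanning [min−3h, max+3h]) of a Gaussian-kernel density with bandwidth
  h = φ·0.9·min(sd, IQR/1.349)·k^(−1/5), φ = 1 by default. When one of the two
  scale candidates is zero but the ratios still differ (e.g. IQR = 0 with an
  outlier), the minimum is taken over the positive candidates; when all ratios
  coincide the common ratio is returned outright.

Median and mode standard errors come from a parametric bootstrap (default
1,000 draws): both beta vectors are resampled from Normal(β̂, se²) — exposure
ses included, which the synthetic generator always provides — and the se is
the sd of the re-estimates. Bootstrap seeds are derived deterministically from
the study seed and the analysis label, so whole-pipeline runs are
byte-reproducible. P-values for median/mode are two-sided normal.

ORs are exp(β) with 95% CI exp(β ± 1.959964·se), rendered to 2 decimals (full
precision kept internally).

## Sensitivity

Cochran's Q = Σ wj (ratioⱼ − β̂_IVW)², chi-square on k−1 df under homogeneity;
it is computed from IVW residuals (Rucker's Q′ is out of scope) and equals the
sum of squared weighted IVW residuals exactly, which is unit-tested.
Heterogeneity and pleiotropy flags use p < 0.05 (configurable).

## Pipeline rules

* **Positive-control gate.** Every target is first tested against a
  control outcome with an established causal relationship. Targets whose
  FDR-adjusted control p (BH across targets) is ≥ α, or whose estimate fails
  the reliability rule, are excluded from every later stage. FDR-adjusted
  rather than raw p keeps the gate consistent with the multiplicity handling
  used everywhere else.
* **Reliability.** An estimate is reliable when the IVW (or Wald, if k = 1)
  p < 0.05 and its sign agrees with MR-Egger's slope. Single-instrument sets
  cannot fit Egger; they pass on significance alone and are listed as
  "direction-unverified" in the manifest.
* **FDR families.** Adjustment is applied within each outcome, across all
  exposure tests against that outcome (configurable to one global family); the
  family key is recorded in the run manifest. Adjusted values are attached to
  the primary-method rows.
* **Mediation.** β₁ (target→mediator), β₂ (mediator→outcome) and β₃
  (target→outcome) are the primary-method estimates; the proportion
  β₁β₂/(β₃+β₁β₂) is computed only for triples whose three betas are
  significant at raw p < 0.05 (configurable to FDR-adjusted). No standard
  error is attached to the proportion by default. The internal identities
  (indirect = β₁β₂ exactly, total = β₃ + indirect exactly) are asserted.
* **β₃ terminology.** The printed formula calls β₃ the "direct" effect, but it
  is the unadjusted step-1 estimate, which in single-exposure MR is the total
  effect: with generative total T and mediated part β₁β₂ the computed
  proportion is β₁β₂/(T+β₁β₂) rather than β₁β₂/T. The package implements the
  printed formula exactly; at the effect sizes of interest here the two differ
  by under one percentage point (8.0% vs 8.8% at the default generative
  values), well inside the Monte-Carlo tolerance used in validation. Multiple
  mediators are handled by iterating the single-mediator formula over triples
  sharing β₃.

## Synthetic data generator

The generator works at the summary-statistic level. For a locus of m SNPs with
MAFs ~ Uniform(maf range) and signed AR(1) correlation r_ij = ρ^|i−j|, sparse
standardized causal effects γ ~ N(0, γ_sd²) on a random subset of SNPs give
marginal (LD-convolved) effects β_marg = Rγ. The mediator responds with
β₁·β_marg (plus optional mediator-specific noise), the outcome with
(direct + β₁β₂)·β_marg plus optional per-SNP pleiotropy
N(pleiotropy_mean, pleiotropy_sd²). Observed betas are Normal(true, se²) with
the standard asymptotic ses 1/√(2f(1−f)n) (quantitative) and
1/√(2f(1−f)·n·φ(1−φ)) (binary with case fraction φ); p-values come from the
observed z. Allele pairs are drawn from the non-palindromic set plus a
configurable palindromic fraction, and the effect allele is randomized to
either frequency side, so harmonization is exercised realistically.

Because the outcome responds to the *sum* of the direct and mediated paths,
MR at the exposure locus recovers the generative total effect
direct + β₁β₂ — asserted in the tests, and the basis of the β₃ discussion
above.

A full study composes two (optionally three) independent loci: the target
locus; a mediator locus where the mediator has its own cis effects (scale
`mediator_gamma_sd`) and the outcome responds via β₂ alone — this second locus
is what makes β₂ identifiable, since at the target locus mediator and outcome
effects are proportional with ratio total/β₁, not β₂; and optionally a second
target locus with a null control effect, to exercise the gate. Trait tables
span all loci with null true effects where a locus does not influence a trait,
like real genome-wide summary files.

**Default study conditions.** The defaults mirror the data sources this design
is used with: a very large quantitative lipid GWAS (n = 439,214), a small
plasma-protein mediator GWAS (n = 3,301), a binary lung-cancer outcome GWAS
(n = 40,187, case fraction 0.578, an ever-smoker-like subgroup), and a binary
CHD-like positive control (n = 86,995, case fraction 0.256, control effect
−0.45 log-odds per SD). The small mediator GWAS matters structurally: with it,
target-locus SNPs never reach genome-wide significance for the mediator (as in
the real protein data), so step-2 instruments come only from the mediator's
own locus. Causal-chain defaults β₁ = 0.24, β₂ = −0.08, direct = −0.20 give a
generative mediation proportion β₁β₂/(direct+β₁β₂) ≈ 8.8%. Locus defaults:
100 SNPs at 1-kb spacing, 20 causal, ρ = 0.8, γ_sd = 0.1 for lipid effects and
0.5 for the protein's own cis effects (cis-pQTLs are characteristically
strong).

**What the generator does not emulate** — and what passing tests therefore do
not establish about real data: realistic human LD (AR(1) only), winner's-curse
effects of discovery-based instrument selection, sample overlap between the
GWAS, population stratification, and trait-scale misspecification. The
validation shows the *procedure* is correct and calibrated under its stated
assumptions, not that those assumptions hold in any particular cohort.

## Validation problem sizes

Calibration uses 500 replicates of a 30-SNP, LD-free locus (all SNPs causal,
γ_sd = 0.15, all GWAS n = 100,000, no pleiotropy), feeding all 30 SNPs to the
estimators directly so that estimator calibration is isolated from selection
effects (selection has its own tests). IVW 95% CI coverage of the generative
total effect and the type-I error of Q and of the Egger intercept test are
checked against 0.95 ± 0.03 and 0.05 ± 0.02. Mediation recovery uses 200
replicate two-locus studies at the default conditions with the pipeline
restricted to IVW + MR-Egger (the estimators the mediation betas and the
reliability rule actually consume; the bootstrap-based estimators are
validated in their own single-run tests), requiring the mean recovered
proportion within 3 percentage points of the 8.8% analytic truth. Observed
values in this configuration: coverage ≈ 0.97, Q type-I ≈ 0.06, Egger type-I
≈ 0.03, mean recovered proportion ≈ 8.5%.

## Known limitations

* LD is an input (or synthetic); the package never computes it from genotypes,
  and proxy-SNP lookup, multi-allelic sites, Steiger filtering, MR-PRESSO,
  multivariable MR and correlated-mediator network mediation are out of scope.
* Exposure-side noise is ignored in the ratio weights (first-order weighting);
  with weak instruments this mildly inflates Q, which is why the F > 10 filter
  is on by default.
* Trait units are declared per trait in configuration and never rescaled or
  inferred; OR conversion is intentional, driven by the declared trait type.
* The mediated-proportion estimator inherits the β₃ total-vs-direct convention
  discussed above; its bias is bounded by the size of the mediated path
  relative to the total effect.
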