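# Methods

## Model and estimands

For instrument j the observed summary statistics are modelled as

    β̂ₓⱼ ~ N(γⱼ, se²ₓⱼ)            (variant–exposure association)
    β̂ᵧⱼ ~ N(θ·γⱼ + αⱼ, se²ᵧⱼ)     (variant–outcome association)

where γⱼ is the true instrument strength, θ the causal effect of the exposure
on the outcome, and αⱼ a direct (horizontally pleiotropic) effect that
bypasses the exposure. A valid instrument has αⱼ = 0. Exposures are analysed
per 1-SD increase (continuous traits) or per unit increase in log odds
(binary traits); with a binary outcome exp(θ) is an odds ratio.

The two-sample design assumes non-overlapping exposure and outcome GWAS
samples from comparable populations, and the three instrumental-variable
conditions: relevance, independence from confounders, and exclusion
restriction. The estimators differ in how they relax the third.

## Instrument preparation

- **Significance filter**: p < 5×10⁻⁸ (configurable).
- **Exclusion list**: variant identifiers removed for known pleiotropy (for
  example a blood-group locus associated with many cancers through pathways
  unrelated to the exposure).
- **LD pruning**: greedy, visiting survivors in ascending p-value order
  (ties by variant id) and dropping any variant with R² ≥ 0.01 against an
  already-kept one. Pairs absent from the LD table count as uncorrelated,
  since instrument lists from a published GWAS are normally pre-clumped.
  The greedy rule equals the lexicographically-first maximal independent
  subset under the same ordering, which the tests verify by exhaustive
  enumeration on small instances.
- **Proxies**: an instrument missing from the outcome GWAS is replaced by
  its highest-R² proxy with R² > 0.9 that is present there. The proxy table
  must carry an allele-correspondence sign (+1/−1), which is trusted rather
  than re-derived from haplotypes; harmonization applies that sign directly
  instead of comparing allele labels, because a proxy's alleles generally
  differ from the target's.
- **Harmonization**: effect alleles are oriented so every exposure beta is
  non-negative (the effect allele is the exposure-increasing allele), the
  outcome beta is negated when its effect allele matches the exposure's
  other allele, and strand complements are recognised. Palindromic variants
  (A/T, C/G) cannot be resolved by labels; the default policy aligns them by
  effect-allele frequency — after label alignment, frequencies on opposite
  sides of 0.5 toggle the orientation once more — and drops the variant when
  either frequency is missing or within 0.08 of 0.5. A `drop` policy is also
  exposed. Every removal and substitution is recorded in a provenance log
  with a machine-readable reason code.

## Estimators and numerical choices

- **Wald ratio SE** is first order, se(β̂ᵧ)/|β̂ₓ|, ignoring exposure-side
  uncertainty. This is what makes IVW numerically identical to weighted
  least squares of β̂ᵧ on β̂ₓ through the origin with weights 1/se²ᵧ (the
  equivalence is tested to 10⁻¹⁰ against an independent WLS fit).
- **IVW multiplicative random effects** scales the fixed-effect SE by
  max(1, √(Q/(J−1))): over-dispersion widens the interval, under-dispersion
  is never allowed to shrink it below the fixed-effect SE. Fixed and MRE
  share the point estimate. The MRE model is the default for table-style
  output; both are available.
- **Weighted median** interpolates linearly on the cumulative standardized
  weight polyline sⱼ = (Σᵢ≤ⱼwᵢ − wⱼ/2)/Σwᵢ at s = 0.5. The SE is a
  parametric bootstrap (default 1000 draws of β̂ₓ, β̂ᵧ from their sampling
  normals, seed mandatory in the pipeline for reproducibility).
- **MR-Egger** is weighted linear regression with intercept, weights 1/se²ᵧ,
  closed form; SEs carry the max(1, √(RSSw/(J−2))) over-dispersion factor
  under MRE, and p-values use t with J−2 df. Harmonization's β̂ₓ ≥ 0
  orientation is a precondition (the intercept is otherwise meaningless).
  Egger's slope suffers regression dilution when instrument strengths are
  noisy; the no-pleiotropy recovery simulations show a small attenuation
  toward the null, well inside the Monte-Carlo tolerance at the default
  settings.
- **Reference distributions**: standard normal for IVW and weighted-median
  p-values, t(J−2) for Egger. The 95% CI multiplier is fixed at 1.96 (not
  more digits of Φ⁻¹(0.975)) so OR/CI rows printed at 2 decimals round-trip
  through the CI-reconstruction path.
- **Minimum instrument counts**: 1 (fixed IVW), 2 (MRE), 3 (weighted median,
  Egger), 4 (MR-PRESSO); heterogeneity needs 2. Below the minimum the
  estimators raise; the pipeline logs and skips MR-PRESSO instead of failing
  the pair.

## MR-PRESSO

The global test computes, for each instrument, the leave-one-out
fixed-effect IVW slope θ̂₋ⱼ and the standardized residual
(β̂ᵧⱼ − θ̂₋ⱼβ̂ₓⱼ)²/se²ᵧⱼ; the observed residual sum of squares is compared
with 1000 (default) simulated datasets drawn under the no-pleiotropy
expectation, with add-one smoothing so the empirical p is never 0 and is
floored at 1/(n_sim+1). The outlier test compares each instrument's observed
squared residual with its own simulated residuals, Bonferroni-multiplies by
J and caps at 1; outliers are declared only when the global test rejects at
0.05, preventing spurious removal under homogeneity. Note the Bonferroni
floor J/(n_sim+1) must clear the outlier alpha — with the defaults
(J ≤ 50, n_sim = 1000) it does. The corrected estimate is IVW on the
non-outlier subset; the distortion test compares the percent change of the
estimate against removal of random same-size subsets. Leave-one-out slopes
use fixed-effect weights throughout, so the residual definition is a single
deterministic slope.

## Sensitivity-analysis trigger and meta-analysis

The pipeline always runs IVW; when its p-value falls below 0.05 (or the
outcome is flagged `always_sensitivity`, e.g. an overall-cancer style
endpoint), it adds weighted median, MR-Egger and MR-PRESSO. IVW is the gate
because it is the only estimator run unconditionally. No multiple-testing
adjustment is applied across a panel; results are meant to be read as
patterns across related exposures rather than dichotomised by threshold.

Cohorts listed in a meta group are combined by fixed-effect inverse-variance
meta-analysis on the log-OR scale. Two input routes share the same
combiner: internally computed estimates, and published rows reconstructed
from "OR (95% CI)" via log-SE = (ln CI_high − ln CI_low)/3.92. Reconstruction
from 2-decimal printed ORs carries ~±0.005 rounding error per input, so
combined point estimates reproduce to 2 decimals while CI end digits can
differ by one; zero-width intervals are flagged degenerate and rejected by
the combiner. Case and non-case counts are passed through and summed in
combined rows.

## Synthetic data

The generator draws γⱼ ~ N(0.02, 0.01²) SD per allele with se_x = 0.003 by
default — stylized values consistent with a GWAS of roughly 70k individuals,
not calibrated to any dataset. Direct effects αⱼ are zero for valid
instruments and N(pleiotropy_mean, pleiotropy_sd²) for the configured
invalid fraction. Allele pairs follow a transition-biased substitution
spectrum (A↔G and C↔T each 1/3), making ~1/6 of variants palindromic;
outcome records are randomly allele-swapped and strand-complemented so
harmonization is always exercised. Effect-allele frequencies are kept at
least 0.10 from 0.5, so palindromic variants remain frequency-resolvable —
real data contain ambiguous palindromic variants that would be dropped,
which the generator deliberately avoids so instrument counts stay exact.
Panels with fixed instrument counts use rejection sampling on the observed
exposure p-values (`ensure_significant`), which mimics selecting
genome-wide-significant hits and introduces the same mild winner's-curse
flavour real instrument lists have.

The four-exposure demonstration panel (61/8/8/31 instruments; the first
including one designated pleiotropic-locus variant for exclusion-list
testing; binary-scale exposures use stronger per-allele effects with larger
SEs) emits two outcome cohorts per exposure, the second missing a few
variants with a proxy table covering some, to exercise proxy substitution
and meta-analysis. A master seed fans out to per-dataset seeds through
`numpy.random.SeedSequence` with fixed counters, so adding datasets never
perturbs existing ones, and all outputs are byte-identical under a repeated
seed.

What passing tests on this generator do **not** show: robustness to
allele-frequency mismatch between cohorts, sample overlap, population
stratification, realistic minor-allele-frequency spectra or LD structure
(LD is only emitted as idealized block tables), winner's curse beyond the
significance filter, or non-linear causal effects.

## Simulation sizes

The recovery and operating-characteristic checks use 300–500 replicates of
60-instrument datasets and 100–200 replicates for the MR-PRESSO error rates,
with 1000 null simulations per test — sizes chosen so Monte-Carlo error is
a small fraction of each tolerance while the whole suite runs in seconds.

## Known limitations

- Wald SEs are first order; second-order (exposure-uncertainty) SEs are out
  of scope.
- No mode-based estimators, multivariable MR, Steiger filtering, or
  correlated-instrument generalized IVW.
- LD and proxy information is consumed, never computed: no genotype panels,
  no liftover, no multi-allelic variants.
- The meta-analysis is fixed-effects only, matching the single-effect
  assumption of combining two cohorts measuring the same population effect.
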