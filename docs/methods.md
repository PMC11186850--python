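# Methods

This note records the models behind `pwmr`, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical choices that affect results.

## The causal model and its assumptions

The pipeline estimates the effect of a circulating protein (exposure X) on a
binary disease outcome Y using genetic variants G as instruments, under the
three instrumental-variable assumptions: relevance (G associates with X),
independence (G is independent of confounders of X→Y), and exclusion
restriction (G affects Y only through X). All inputs are marginal summary
statistics: per-variant effect sizes, standard errors, allele frequencies and
p-values from non-overlapping exposure and outcome samples (two-sample MR).
Binary-outcome effects are log odds ratios throughout; causal estimates for a
binary outcome are log-odds per unit (here, per SD) of exposure, reported
alongside OR = exp(β).

Restricting instruments to the cis region of the protein-coding gene is the
key design defence of the exclusion restriction: a variant near the gene that
alters the protein's level has a short, biologically direct path to the
exposure, making horizontal pleiotropy less likely than for trans signals.
The remaining threats — correlated pleiotropy, linkage of distinct causal
variants, reverse causation, confounder-driven instruments — are each handled
by a dedicated stage (Egger intercept, HEIDI/coloc, Steiger + reverse MR,
confounder-exclusion sensitivity analysis).

## Stage-by-stage choices

### Instrument selection (`pwmr.instruments`)

Thresholds (all configurable through `SelectionParams`): association
p < 5×10⁻⁸; cis window = gene start/end ± 500 kb, 1-based inclusive
coordinates (anchoring to the gene body rather than the TSS gives a superset
of TSS-anchored windows); MAF ≥ 0.01 computed as min(eaf, 1−eaf) from the
exposure study and applied to the instruments themselves as well as being the
reference-panel convention; palindromic variants dropped when the *exposure*
allele frequency is in [0.4, 0.6] (instrument-side data are always present,
outcome frequencies often are not); HLA exclusion chr6:29,000,000–34,000,000
(build-agnostic input); greedy clumping at r² < 0.001 within 10 Mb with a
deterministic (p-value, variant id) tie-break. Every exclusion is logged in
an audit trail with the rule that removed it. Per-variant instrument strength
uses F = z² = (β/se)², the standard approximation when only marginal
statistics are available.

### Harmonization (`pwmr.harmonize`)

Outcome records are re-oriented to the exposure's effect allele, accepting
direct or strand-complement matches and negating β / complementing the
frequency on allele swaps. Palindromic variants cannot be strand-resolved
from alleles alone, hence the intermediate-frequency drop; outside that
window they are aligned assuming same-strand reporting. Indels and
multi-allelic records are rejected at load. Missing outcome variants may be
rescued by the best LD proxy with r² ≥ 0.8; the proxy's effect is re-oriented
by the sign of the LD correlation (allele bookkeeping for both query and
proxy goes through the LD reference's allele orientation, since the two
variants' allele pairs are not comparable directly). Harmonization is
idempotent, and all downstream estimators are invariant to allele recoding of
any input file.

### Estimators (`pwmr.estimators`)

- The Wald-ratio SE uses the first-order delta method (se_y/|β_x|), matching
  the IVW weight definition; a second-order option adding the exposure-side
  term is available but not default.
- Random-effects IVW inflates the fixed-effect SE by max(1, √(Q/(k−1))) —
  multiplicative with floor 1, never deflating below the fixed-effect SE.
  Under the null with valid instruments the fixed-effect z is the exact
  pivot (p-values exactly uniform); the floor makes the random-effects
  p-values mildly conservative (rejection at or below α), which is the
  intended direction of error. Calibration checks test the exact pivot for
  uniformity and the random-effects variant for non-anti-conservatism.
- MR-Egger first orients all exposure effects non-negative, fits a weighted
  regression with intercept, and inflates both SEs by max(1, √(Q/(k−2))).
  Inference is normal-based, as for the other estimators: the floor already
  makes the intercept test mildly conservative (measured type-I error ≈ 0.04
  at α = 0.05 with 20 instruments), and stacking a t(k−2) correction on top
  over-corrects (≈ 0.03).
- Weighted median: inverse-variance weights on the ordered ratios, linear
  interpolation at cumulative weight 0.5; weighted mode: Gaussian-kernel
  density argmax with a weighted Silverman bandwidth (512-point grid).
  Both report seeded parametric-bootstrap SEs (default 1,000 draws); seeds
  are explicit arguments so pipeline runs are reproducible.
- Steiger: per-variant variance explained r² = z²/(z² + n − 2); trait-level
  r = √(Σr²) over the instruments, capped at 1; inference via
  Fisher-transformed correlations. For binary outcomes this is the
  observed-scale approximation from the log-odds z-score — no
  liability-scale conversion is attempted, and output labels it as such.

### GSMR and HEIDI (`pwmr.gsmr`, `pwmr.heidi`)

GSMR instruments come from relaxed clumping (r² < 0.1) so the GLS has enough
variants; per-variant ratio variances include the exposure-side term
v_j = (se_yj² + b̂_xy,j² se_xj²)/β_xj², which is what distinguishes GSMR's
weights from plain IVW. The outlier loop removes the worst variant while its
standardized deviation from the current estimate (variance v_j − var(β̂),
floored at 10⁻¹²) has p < 0.01, refitting each round; it terminates in at
most k iterations and raises a degenerate-fit error rather than continue
with fewer than two variants.

HEIDI takes the smallest-exposure-p variant as the top signal and tests the
joint deviation of ratio estimates d_j = b̂_xy(j) − b̂_xy(top) across 3–20
region variants with exposure p ≤ 1.57×10⁻³, pruning candidates with
r² > 0.9 (near-duplicates of the top variant carry no information) or
r² < 0.05 (off-signal) against it — the published defaults of the
SMR/HEIDI framework. The statistic T = Σ z_dj² is a quadratic form in
correlated normals; its tail probability comes from numeric inversion of the
characteristic function (Imhof's integral, evaluated piecewise over segments
short enough to bound the oscillation count, truncated where the integrand's
envelope falls below 10⁻¹¹), with Satterthwaite moment matching as a
fallback when the integration fails its own error check.

Interpretation: a *small* HEIDI p-value rejects the single-shared-variant
model (it indicates linkage of distinct causal variants), so p ≥ 0.05 is the
passing outcome and is what the tier rules require. Published descriptions
of the test occasionally state the opposite reading; the reported tier-1
associations (all with p_HEIDI ≥ 0.05) are consistent with the convention
used here.

### Colocalization (`pwmr.coloc`)

Wakefield log-ABFs per variant and trait from (β, se) only; the MAF-based
variance reconstruction is not implemented. Per-trait prior effect SDs
default to 0.15 for quantitative traits and 0.2 (log-odds) for binary
traits — the standard defaults of the framework — and are configurable;
hypothesis priors default to p1 = p2 = 10⁻⁴, p12 = 10⁻⁶. All sums are done
in log space (log-sum-exp; the H3 term via a stable log-difference), and the
five posteriors are validated against explicit enumeration over every causal
configuration to 10⁻¹⁰. The single-causal-variant-per-trait assumption is
intrinsic and recorded in every result object. Support labels: PP.H4 ≥ 0.80
strong, ≥ 0.50 moderate.

### Pipeline and tiers (`pwmr.pipeline`)

BH-FDR is computed jointly across all protein×outcome discovery tests (one
family), via `statsmodels.stats.multitest`. Discovery uses the Wald ratio
for a single instrument and random-effects IVW otherwise; validation
requires p < 0.05 with the discovery direction; "suggestive" means p < 0.05
in both pQTL studies with the same direction. Confirmation runs GSMR on the
r² < 0.1 instruments when at least `gsmr_min_snps` (default 5) survive,
LD-aware IVW for 2–4, and reports `insufficient_snps` otherwise;
heterogeneity (Cochran Q) and pleiotropy (Egger intercept) diagnostics are
computed on the same relaxed instrument set. Colocalization is run for both
the discovery and validation exposure against the outcome region and the
maximum PP.H4 is kept.

The sensitivity analysis refits the MR after removing variants listed in a
user-supplied confounder-association table (the stand-in for an external
pleiotropy-database query), re-clumping at r² < 0.001; optional pre-filters
(outcome p < 5×10⁻⁸ removal, cross-cohort heterogeneity) apply only when
the corresponding inputs are provided, since they require multi-cohort
outcome data.

Reverse MR swaps the roles: outcome loci (selected and clumped per region at
p < 5×10⁻⁸, relaxed to 10⁻⁵ when nothing qualifies) instrument the outcome,
and their joint effect on the protein is estimated. The protein's own cis
window is excluded from the reverse instruments: under any true forward
effect the shared cis variant would associate with both traits and mimic
reverse causation, so including it makes the test uninformative. A reverse
p < 0.05 raises a flag.

Tier rules, as encoded (thresholds in `TierCriteria`): a
discovery+validation-significant record is tier 3 if PP.H4 < 0.5 or the
sensitivity or confirmation analysis failed; else tier 1 if PP.H4 ≥ 0.8,
HEIDI p ≥ 0.05, heterogeneity and pleiotropy p ≥ 0.05 (a not-assessable
diagnostic counts as clean by default; a strict mode is available), and the
protein is significantly/suggestively associated with ≥ 2 outcomes; else
tier 2. Suggestive-only records are graded tier 3. An unassessable HEIDI
does not qualify for tier 1. The tier-2/3 boundary was reconstructed from
the published association table and reproduces all 22 printed tiers; it is
an editable rule, not hard-coded logic. `insufficient_snps` confirmation is
treated as not-failed (it is a data-availability outcome, not evidence
against the association).

## The synthetic-data generator

`pwmr.simulate` works on the standardized-genotype scale. A region of m
variants has LD correlation R (AR(1), constant-correlation blocks, or
identity — all PSD by construction; block correlations are restricted to
[0, 1)). Given joint effects b, the true marginal z-scores are √n·R·b and
observed z-scores are drawn from MVN(√n·R·b, R) — the exact sampling
distribution of marginal GWAS statistics for standardized genotypes and
large n. Emitted files convert to the per-allele scale with
se = 1/√(n·2f(1−f)) and β = z·se, with allele frequencies drawn uniformly
and non-palindromic allele pairs, so outputs pass the package's own IO
validation. Binary outcomes use the effective sample size
n_eff = 4/(1/n_cases + 1/n_controls) on the log-odds scale.

Causal architectures: exposure-only (H1), outcome-only (H2), distinct
variants (H3), shared variant with causal effect (H4), directional
pleiotropy, 40%-invalid instruments, reverse causation (the outcome's
genetic effects leak into the exposure), and a confounder-acting variant
with both a strong exposure association and a direct outcome effect.
Preset effect sizes are fixed study conditions: a cis-pQTL joint effect of
0.3 SD per allele-SD (≈9% of protein variance — strong, as cis-pQTLs
typically are), causal effect 0.25 log-odds per SD protein for
strong-signal scenarios, and outcome-locus effects of ~0.1 SD. The
`paper_like` scale uses exposure n = 35,559 and 79,495/1,259,808
cases/controls divided by 40 (a full-scale flag restores the printed
counts); `small` uses 5,000 / 2,000 / 20,000. The 40× reduction keeps
desk runs fast while preserving z-score magnitudes of the same order as
the full-scale study for the larger preset effects.

The study-level generator lays one cis region per protein on its own
chromosome plus dedicated outcome-only loci, and emits genome-wide summary
statistics per protein (null outside the own cis region) — this coverage is
what makes reverse MR and cross-region operations meaningful. Discovery and
validation pQTL samples are independent draws at n = 7,213 and 35,559.

An individual-level generator (latent-Gaussian haplotypes thresholded at the
allele-frequency quantile, additive exposure, logistic outcome with the
intercept set to the configured case fraction) serves as an independent
oracle: its per-variant marginal regressions agree with the summary-level
expectations. Note the thresholding attenuates the latent correlation, so
realized dosage LD sits slightly below the target R off the diagonal;
expectation identities hold exactly with the realized LD, and the
cross-generator test therefore uses independent variants.

What the generator does *not* emulate: realistic recombination-map LD,
population structure, sample overlap between exposure and outcome studies,
assay measurement error and batch structure, liability-scale subtleties of
case ascertainment, or genome-wide polygenic background. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated sampling model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

- LD matrices are ridge-regularized, (R + λI)/(1 + λ) with λ = 10⁻³, before
  any inversion (reference panels give near-singular matrices); the unit
  diagonal is preserved.
- Wald ratio with β_x = 0 raises; IVW with one variant signals to use the
  Wald ratio (the pipeline does this automatically); Egger/median/mode need
  ≥ 3 variants; cross-cohort heterogeneity with one cohort is flagged
  not-assessable rather than invented.
- Clumping treats variants missing from the LD reference as correlated with
  nothing (retained, flagged `ld_missing`).
- Monomorphic variants are excluded from dosage-based LD with a warning.
- All tie-breaks (clump index choice, HEIDI top variant) are deterministic
  via (p-value, variant id) ordering; pipeline tables are written with fixed
  float formatting, so identical configs and seeds give byte-identical
  outputs.

## Problem sizes used by the test and acceptance suites

Calibrations run at 2,000 replicates (IVW null uniformity, Egger intercept
type-I), 1,000 (HEIDI type-I under a shared causal variant), 200
(colocalization H4/H3 scenario rates, GSMR recovery and outlier removal,
IVW recovery) and 500 (Steiger directionality at n = 50,000); the null
proteome FDR study uses 60 runs of 10 proteins. These sizes give Monte-Carlo
standard errors a few times smaller than the width of each assertion band.

## Known limitations

- Steiger r² for binary outcomes is the observed-scale z-based
  approximation.
- The weighted-mode bandwidth rule is a pragmatic weighted Silverman
  variant; mode estimates on very few instruments are grid-limited.
- The sensitivity stage models confounder knowledge as a static exclusion
  table; querying association databases is out of scope.
- Colocalization assumes at most one causal variant per trait per region;
  regions with allelic heterogeneity dilute PP.H4.
- Proxy lookup uses the single best proxy; no multi-proxy imputation.
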