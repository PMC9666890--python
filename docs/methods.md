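# Methods

## Model and assumptions

mrkit implements summary-data two-sample Mendelian randomization. For
SNP j the exposure GWAS reports (γ̂ⱼ, σ_Xⱼ) and the outcome GWAS
(Γ̂ⱼ, σ_Yⱼ), assumed independent across samples and, after LD clumping,
across SNPs. The working model is

    Γⱼ = β·γⱼ + αⱼ

with β the causal effect and αⱼ a horizontal-pleiotropy effect, zero for
a valid instrument. The three instrumental-variable conditions are:
relevance (γⱼ ≠ 0, screened by genome-wide significance and the
F-statistic), independence from confounders (supported by the
confounder-trait exclusion list), and exclusion restriction (αⱼ = 0,
probed by the Egger intercept and MR-PRESSO).

## Estimators and numerical choices

**Wald ratio.** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ, SE σ_Yⱼ/|γ̂ⱼ| — the first-order delta
approximation that ignores exposure-side noise. With the strong
instruments the selection chain produces (F ≈ 100 at the default
generator settings) the neglected second-order term is below 1% of the
ratio variance.

**IVW.** The precision-weighted mean of the ratios, algebraically a
weighted regression of Γ̂ on γ̂ through the origin with weights σ_Yⱼ⁻².
The random-effects variant is *multiplicative*: same point estimate,
SE scaled by max(1, √(Q/(J−1))). We chose the multiplicative model over
additive (DerSimonian–Laird) random effects because result tables in
this literature show identical fixed/random point estimates, which only
the multiplicative model guarantees. The scale factor is floored at 1
(no super-efficiency under Q < J−1).

**Weighted median.** Order the ratios, form standardized midpoint
cumulative weights sⱼ = (Σ_{k≤j}w_k − wⱼ/2)/Σw, interpolate β̂ across s
at s = 0.5. The SE uses a parametric bootstrap (default 1000 replicates,
each β̂ⱼ redrawn from N(β̂ⱼ, seⱼ²)); a closed-form density-based SE
exists but the bootstrap is the simpler defensible choice and is exactly
reproducible under the recorded seed.

**MR-Egger.** Instruments are first oriented so γ̂ⱼ ≥ 0 (the fit must
not depend on arbitrary allele coding), then Γ̂ = α + βγ̂ is fit by WLS
with weights σ_Yⱼ⁻². Coefficient SEs carry the multiplicative
overdispersion factor max(1, √(RSS_w/(J−2))). All p-values in the
package — IVW, median, Egger — use the normal distribution rather than
t; with the J ≈ 40–60 instruments the pipeline targets, the difference
is a third decimal in p, and the normal choice keeps every estimator's
inference consistent. Degenerate designs (J < 3, all γ̂ equal) are
rejected rather than silently regularized.

**Cochran's Q.** Q = Σwⱼ(β̂ⱼ − β̂_IVW)² on the fixed-effects fit,
referred to χ²_{J−1}. Q is computed on IVW (not Egger) residuals, the
standard choice. The pipeline's decision rule: fixed-effects IVW is the
primary estimate when the Q-test p exceeds `q_alpha` (default 0.05),
random-effects otherwise; both rows are always reported.

**MR-PRESSO.** For each SNP the leave-one-out IVW estimate β̂₍₋ⱼ₎ gives
residual rⱼ = Γ̂ⱼ − γ̂ⱼβ̂₍₋ⱼ₎ and the observed statistic
RSS = Σwⱼrⱼ², wⱼ = σ_Yⱼ⁻². The null distribution is parametric: K
replicates (default 1000) redraw γ̂*ⱼ ~ N(γ̂ⱼ, σ_Xⱼ) and
Γ̂*ⱼ ~ N(γ̂ⱼβ̂₍₋ⱼ₎, σ_Yⱼ) and recompute RSS identically (leave-one-out
estimates re-derived from the simulated data). All Monte Carlo p-values
use the (1 + #exceedances)/(K + 1) form, so they are never zero and are
reproducible under a fixed seed. Per-SNP outlier p-values compare each
SNP's observed weighted squared residual to its simulated distribution,
flagged at the Bonferroni threshold 0.05/J — note K must be at least
J/0.05 for the Monte Carlo floor 1/(K+1) to undercut that threshold
(K = 1000 covers J ≤ 50). The distortion test compares the
outlier-removal shift of the IVW estimate against the shift from
removing equally many random SNPs. The corrected estimate is plain
fixed-effects IVW on the retained subset, bit-identical to calling the
IVW routine on those instruments; with no outliers flagged the corrected
row equals the full-panel IVW, matching how published tables report
MR-PRESSO when nothing is removed.

## Harmonization policy

Outcome records are aligned to the exposure's effect allele through a
truth table: direct match; swapped effect/other alleles (negate Γ̂, flip
eaf); strand complement; complement plus swap. Palindromic (A/T, C/G)
variants cannot be resolved from alleles alone: they are kept only when
both studies report allele frequencies, both lie outside
0.5 ± `palindrome_eaf_window` (default 0.08), and the frequencies agree
on an orientation; otherwise dropped with a reason code. Indels and
multi-allelic records are rejected at read time; chromosome is stored as
a string and positions are 1-based. Harmonization is idempotent and
every drop is logged, never fatal.

## LD clumping

Greedy index-SNP selection: repeatedly take the smallest-p remaining
candidate, remove every candidate on the same chromosome within
`window_kb` whose r² against the index is ≥ `r2_threshold`. p-value ties
break lexicographically by rsid, making the output invariant to input
order. The implementation takes a precomputed r² matrix (TSV) instead of
genotypes; when no matrix is supplied, distance alone prunes, and a
candidate absent from a supplied matrix is removed whenever it is inside
the window (conservative). The Bonferroni denominator for the
outcome-association filter is the instrument count entering that filter
(counts differ per outcome after harmonization); removal requires
p strictly below 0.05/J. Weak instruments (F ≤ 10) are flagged but only
removed on request, since the intended use case is panels whose F
values sit far above the bar.

## The synthetic-data generator

`simulate_study` emulates paired summary statistics for a binary
exposure at biobank scale against a quantitative outcome: per SNP a maf
pⱼ ~ U(0.05, 0.5), true effect γⱼ ~ N(0, var_gamma), sampling SDs
σ = (2p(1−p)n)^(−1/2) on the standardized scale (per-SD outcome,
per-log-odds exposure), observed effects drawn normally around the
truth, and alleles drawn uniformly so palindromic pairs occur at their
natural 1/3 rate. Defaults mirror the motivating study design:
n_exposure = 218,754, n_outcome = 35,648, J = 55 instruments,
var_gamma = 10⁻³ (median F ≈ 100, comfortably above the >31 floor such
panels exhibit). By default the panel is rejection-sampled to pass
p < 5×10⁻⁸ — the winner's-curse conditioning a real selection pipeline
induces — and the stored truth refers to the post-selection panel; the
residual IVW attenuation this causes is ≈ 0.003 at the default strength,
visible in the recovery summaries (mean estimate ≈ 0.117 for truth
0.12).

Pleiotropic effects are defined on the *oriented* (exposure-increasing
allele) scale: allele coding is arbitrary, so "directional pleiotropy
with mean μ_α" is only meaningful relative to each SNP's exposure-effect
direction. The generator draws αⱼ ~ N(μ_α, σ_α) for a π-fraction of
SNPs on that scale and maps back via sign(γⱼ). An optional InSIDE
violation adds a component proportional to |γⱼ|. Between-sample eaf
jitter (SD 0.01) exercises the palindrome-resolution path, and
`scramble_outcome_representation` randomly re-expresses outcome allele
codings to exercise the full harmonization truth table.

`plant_outliers` injects k outliers of `magnitude` outcome-SEs. Its
`direction` flag matters: `raw` adds +magnitude·σ_Y on the reported
allele coding — with mixed γ̂ signs the induced ratio shifts partly
cancel (balanced-ish pleiotropy), which is the clean setting for testing
*detection* (the exact planted set is flagged in ≈ 92% of reps at k = 3,
magnitude 10, J = 50). `aligned` multiplies by sign(γ̂ⱼ), producing
genuinely directional pleiotropy that biases IVW — the setting for
testing *bias reduction* (the corrected estimate beats the uncorrected
in ≈ 95% of reps). Under aligned planting the induced bias leaks into
clean SNPs' leave-one-out residuals and the exact-set detection rate
drops to ≈ 0.88; this is a property of the residual-simulation procedure
itself, not of the implementation.

What the generator does **not** emulate: genuine LD between the effect
estimates (the AR(1) r² matrix is selection metadata only — effects are
drawn independently), sample overlap between the two GWAS, allele-
frequency differences between ancestries, untyped-variant proxies, and
binary-trait liability-scale subtleties. Passing tests therefore
demonstrate correctness of the estimators and decision rules under the
standard two-sample model, not robustness to those real-data
complications.

## Problem sizes in the validation suite

The repeated-simulation checks use: parameter recovery and CI coverage
over 500 studies of 55 instruments; test calibration over 1000 null
studies of 50 instruments (PRESSO global with K = 500 per study);
outlier detection and bias reduction over 200 studies each (K = 1000,
needed so the Bonferroni threshold 0.05/50 is reachable); LD-clumping
audits over 100 random 30-SNP AR(1) panels; the analysis drivers use
smaller rep counts of the same checks. These sizes give Monte Carlo
standard errors well inside the acceptance bands (e.g. ±0.007 on a 0.05
rejection rate at 1000 reps).

## Known limitations

- No mode-based, MR-RAPS, contamination-mixture or multivariable
  estimators; no reverse-direction or Steiger filtering.
- No VCF input, liftover, proxy-SNP lookup, or live trait-catalogue
  queries; exclusion lists and LD matrices are user-supplied files.
- The Egger normal-theory p-values are mildly anti-conservative at very
  small J; below ~10 instruments a t-reference would be more cautious.
- The weighted-median bootstrap SE underestimates slightly when J is
  very small (< 5), where the estimator itself is of limited value.
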