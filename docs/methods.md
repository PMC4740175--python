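# Methods

## The measurement and its scales

A 450K-style array reports, per probe and sample, β = M/(M+U): the fraction
of molecules methylated at the target cytosine, bounded in [0, 1] and
heteroscedastic near the bounds. All descriptive quantities (group means,
Δβ, corridor capture, the classifier threshold) are computed on the β scale,
where numbers have their biological meaning. Statistical testing happens on
M-values, M = log₂(β/(1−β)), after clamping β into [ε, 1−ε] with ε = 10⁻⁶ —
the clamp keeps M finite at degenerate β without materially moving interior
values. Coordinates are 1-based inclusive throughout; BED-style half-open
inputs must be converted by the caller.

The unit of analysis is the cell line. Replicate DNA extracts are averaged
to line level *before* any between-group testing, so "n" in every contrast
is the number of lines, not extracts. This matches the design in which
replicates quantify technical/within-plate variation, not biological
replication of the phenotype.

## Synthetic cohorts: what they emulate, and what they do not

The generator (`cphcap.synthetic`) encodes the study conditions as its
defaults: 15 HDC + 10 LDC hiPSC lines and 6 donor lines with 6 extracts
each; 2,676 CpH probes, 20,000 CpG probes, 59 rs genotyping probes; group
mean CpH β of 0.50 (HDC), 0.37 (LDC), 0.08 (donor); detection p ~ U(0,
0.005); conversion-control intensities consistent with a 99.5% conversion
rate. The 15/10 split of the 25 discovery lines is an assumption (only the
total is pinned down) and is configurable.

On the logit scale, a CpH observation is θ_p + δ_g + ℓ + e with

* θ_p ~ N(0, 0.8): the probe's baseline, a locus property;
* δ_g: a per-group shift, solved by bisection (41-node Gauss–Hermite over
  the noise) so the *expected grand mean of β* — not of logits — hits the
  configured group mean to well under 10⁻⁴;
* ℓ ~ N(0, 0.15): a per-line scalar shared across all CpH probes of the
  line. Making the line effect global to the CpH compartment (rather than
  independent per probe) is deliberate: between-line spread of β_mean is
  what gives the group contrast its realistic uncertainty (a CI spanning
  several percentage points), and it is a line-level property of global
  non-CG methylation. CpG probes deliberately do *not* share a line scalar —
  they get independent per-probe-per-line noise — so CpG probe subsets obey
  the tight null bound the Monte Carlo analysis checks (max |Δβ_mean| well
  under 0.005). One mechanism per compartment, each matching the behaviour
  the analysis relies on.
* e ~ N(0, 0.10): per-probe, per-extract measurement noise.

Because the group effect is a constant logit shift, every CpH probe carries
the same M-scale effect; probes differ in β-scale effect only through the
logistic derivative. Two consequences worth knowing when interpreting test
output: ranking MVPs by p is, on this synthetic data, ranking noise (all
probes are equally non-null), so a top-9 panel behaves like a random CpH
panel rather than an enriched-effect panel; and per-probe CVs across lines
(~0.2 on average) are lower than real-data CVs (~0.5), because real non-CG
variation has probe-specific biological components the generator does not
model. Passing tests therefore demonstrate the *pipeline's* correctness and
calibration, not that real data will show effects of these exact sizes.

rs probes draw a Hardy–Weinberg genotype per line (allele frequency
U(0.2, 0.8)) read out near {0.03, 0.50, 0.97} with 0.01 noise. Genotypes are
drawn per *line*, not per donor individual; real sibling lines share donor
genotypes, which would require a donor-aware identity check. Replication
cohorts (`generate_replication_cohort`) reuse the discovery cohort's probe
parameters (θ_p, δ_g, CpG means) and draw fresh lines — probe effects are
locus properties, and without sharing them a discovery-trained panel could
not transfer, which is the point of a replication design. Array layout
(batch, slide, position) is assigned in randomized order so technical
covariates are unconfounded with phenotype, mirroring randomized
hybridization.

Artifact injection plants three failure modes with a truth registry: failed
probes (detection p resampled from U(0.05, 1) in one extract), swapped
extracts (rs profile replaced by another line's genotypes), and
under-converted samples (β ← 1 − c(1−β), control intensities regenerated at
rate c), enabling exact-recovery tests of each QC stage.

## QC decisions

* **Conversion efficiency.** Background N̄ = mean negative-control
  intensity; adj(X) = max(X − N̄, 0) for each of the three converted (BIC)
  and unconverted (BIU) green-channel controls; efficiency =
  100·Σadj(BIC)/(Σadj(BIC)+Σadj(BIU)). The background-subtract-and-ratio
  form is a reconstruction from the surrounding description of the control
  probes; it is exact under the generator's intensity model (both closed-form
  cases and the scale-invariance property hold identically). Samples below
  90% are excluded by default (configurable); degenerate controls (both
  adjusted sums zero) yield a flagged missing value, never a crash.
* **Detection filtering** uses the standard convention: a probe *fails*
  where detection p > α (α = 0.01) and is excluded if it fails in at least
  one extract. Exclusions are monotone in α by construction.
* **Replicate identity.** For each extract, distance on rs-probe β to its
  own line's centroid (leave-one-out) versus every other line's centroid;
  flagged when another line is strictly closer. This is a deterministic
  surrogate for the visual mis-clustering screen the workflow formalises.
  Leave-one-out keeps a swap from masking itself; centroids keep a swap from
  dragging its source line's genuine extracts into false flags — a plain
  nearest-neighbour rule does both on planted swaps. Single-extract lines
  are uncheckable and reported as skipped.
* **Probe exclusion.** Sex-chromosome probes are excluded (mixed-sex
  cohorts). Variants at the target dinucleotide (positions p, p+1 on the
  probe strand) or within the 10 bases on the single-base-extension side are
  *flagged*, not excluded — they quantify potential confounding. The true 3'
  probe end would need the array manifest; the extension-side window is the
  documented approximation.
* **SVD scan.** Probe-centred matrix, top-k right-singular vectors;
  Kruskal–Wallis for categorical covariates, Pearson for numeric. Extracts
  of a line are correlated, so extract-level p-values for line-constant
  covariates (e.g. sex) run anti-conservative; the scan is a screen for
  technical structure, not a formal test.

## Statistical choices

* **Variance shrinkage.** The prior (d₀, s₀²) is moment-matched on
  z = log s²: solving trigamma(d₀/2) = Var(z) − trigamma(d_g/2) via a
  Newton iteration on the trigamma inverse, then s₀² from the mean of z and
  digamma terms. Probes with d_g = 0 or s² = 0 are excluded from estimation
  (shrinkage still assigns them a finite posterior variance). When the
  spread of log-variances is no wider than sampling noise the prior df is
  infinite and the moderated t degenerates to a z-like statistic at s₀² —
  on homoscedastic synthetic data this is the *correct* outcome, and the
  d₀ → 0 / d₀ → ∞ limits are asserted numerically. Total df is capped at
  the pooled residual df. Agreement with an independent reference
  implementation of the same published estimator is frozen into the suite
  at 10⁻⁶.
* **Group contrast.** Welch (unequal-variance) t on line-level means — the
  two-sample test with the fewer assumptions, since only "two sample t" is
  specified; CI from the t distribution at Welch–Satterthwaite df. Groups
  with fewer than 2 lines yield a flagged, CI-less result.
* **Permutation test.** Labels permuted over lines (the testing unit);
  two-sided on |Δβ_mean| with the add-one estimator p = (1 + #{|null| ≥
  |obs|})/(B+1); switches to exhaustive enumeration (and the exact p) when
  C(n, n₁) ≤ B. Defaults B = 20,000 (permutation) and 10,000 (Monte Carlo)
  keep desk runs interactive; both are configurable upward.
* **Monte Carlo CpG null** samples probe subsets without replacement and
  reports the max |Δβ_mean| and quantiles; β > 0.80 restriction selects
  probes by pooled mean over the contrasted lines.
* **BH q-values** via the standard step-up implementation; `q ≥ p` and
  monotonicity are asserted as properties.

## Classifier

Panel selection takes the k = 9 smallest-p probes from the top-200 MVP pool.
The criterion used for the original panel (assayability on a secondary
platform) is not computable from array data; a `spread` rule (greedy
max-min Δβ separation, seed-deterministic) is provided as an alternative.
Group CIs of the line-level panel mean use the Student t; the threshold is
(LDC upper bound + HDC lower bound)/2. Overlapping CIs still produce a
model, prominently flagged. Ties at the threshold predict HDC —
deterministic, and consistent with signed-deviation reporting in which zero
deviation plots as a (degenerate) positive bar. Note the printed bounds
40% and 52% midpoint to 46.0%; a published 45.8% reflects unrounded bounds,
which are not recoverable from rounded ones — the package always reports
the unrounded midpoint of its own CIs. A line missing more than a third of
panel probes is marked unpredictable rather than silently imputed.

## Corridor comparison

Promoter methylation is the median β of member probes (robust to single
aberrant probes); capture is inclusive at both bounds. "Within 10%/20% of a
bound" is interpreted as absolute β distance ≤ 0.10 / ≤ 0.20 (corridor
bounds are themselves β fractions); a relative-distance variant is a flag
away. The capture denominator is promoter × sample estimates over
pluripotent (hiPSC/hESC) lines by default. CV uses the sample (n−1) standard
deviation over the mean; undefined below 2 non-missing samples or at mean
zero.

## Clustering

Euclidean distance, average linkage by default (the original choice is
unstated; both are configurable). Columns are sorted lexicographically by
line id before linkage so merge-order ties break deterministically. Clade
agreement is majority-vote label assignment at a k-cut plus the adjusted
Rand index; the 3-cut on significant probes separates donor/LDC/HDC cleanly
on synthetic defaults.

## Pipeline

Stage order is fixed: QC → averaging → MVP → contrasts → resampling →
classifier → clustering → corridor. Per-stage random substreams derive from
the single run seed keyed by stage name, so toggling one stage never shifts
another's draws. Optional stages degrade gracefully (no corridor table → no
corridor section); required-stage failures raise a stage-named error
carrying the partial report. The report bundle is validated against the
published JSON schema (`src/cphcap/schemas/report.schema.json`, generated
from the pydantic model that performs the validation).

## Problem sizes in the test suite

The suite runs the full-size default cohort (22,735 probes × 186 extracts)
once as a shared fixture for calibration-dependent checks. Replicated
simulations use deliberately small cohorts — 120–400 CpH probes, 12–14
lines, 2–3 extracts — chosen so that 200-cohort type-I calibration and
20-seed parameter-recovery checks stay interactive while the quantities
being averaged (rejection rates, mean recovered Δ) remain unbiased; the
acceptance script averages the recovered Δβ_mean over 5 full-size cohorts to
report a low-variance estimate of the planted 13-point contrast.

## Known limitations

Raw intensity processing (IDAT parsing, within-array normalization, dye
bias) is out of scope — data enter as β plus control intensities. Epigenetic
age is not computed; reports accept a precomputed per-sample age table.
Variant filtering uses a generic variant table rather than any specific
catalogue. The generator's noise is logit-normal and homoscedastic by
design (it makes moderated-t behaviour analytically checkable) and so does
not reproduce probe-specific variance structure, beta-mixture shapes, or
batch effects of real arrays; batch-effect injection would be a natural
extension.
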