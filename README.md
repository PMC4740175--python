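# cphcap — non-CG methylation as a biomarker of endodermal differentiation capacity

Human induced pluripotent stem cell (hiPSC) lines that pass every standard
pluripotency test can still differ sharply in how well they differentiate
into endoderm. `cphcap` implements the methylation-array analysis behind one
molecular readout of that difference: on Illumina 450K-style data, mean
methylation at non-CG (CpH, H ∈ {A, T, C}) sites is high in lines with high
endodermal differentiation capacity (HDC, β_mean ≈ 50%) and reduced in
low-capacity lines (LDC, β_mean ≈ 37%), while donor fibroblasts sit near 8%.
The package is for stem-cell and epigenomics groups who want to apply,
stress-test, or extend this style of biomarker analysis — every stage runs
on seeded synthetic cohorts, so the full pipeline is testable without any
array data in hand.

## What it computes

Given a probe × sample β matrix (β = methylated fraction, in [0, 1]) with
probe annotation, a sample sheet, and optional control-probe intensities:

* **QC** — per-sample bisulfite conversion efficiency from Infinium-I
  control probes, `100·Σ adj(BICᵢ) / (Σ adj(BICᵢ) + Σ adj(BIUᵢ))` with
  `adj(X) = max(X − N̄, 0)` and N̄ the mean negative-control intensity;
  detection-p filtering (probe dropped if p > 0.01 in ≥ 1 extract);
  replicate-identity checks on rs genotyping probes; sex-chromosome and
  polymorphism probe flags; SVD confounder scan.
* **MVP calling** — replicate extracts averaged to line level, β logit
  transformed to M-values (M = log₂(β/(1−β))), then per-probe moderated
  t-tests: the pooled residual variance s²_g (d_g df) is shrunk toward a
  prior (d₀, s₀²) estimated by moment-matching on log s², giving posterior
  variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and t with d₀ + d_g df;
  Benjamini–Hochberg FDR; hyper/hypo direction from Δβ.
* **Group contrast** — Δβ_mean between HDC and LDC line means with Welch t
  and 95% CI; donor "epigenetic memory" contrasts.
* **Empirical nulls** — label-permutation test for Δβ_mean (add-one
  two-sided p) and a Monte Carlo null sampling CpG probe subsets of the CpH
  panel size (optionally restricted to methylated CpGs, β > 0.80).
* **Nine-probe classifier** — panel from the top MVPs; threshold at the
  midpoint of the LDC upper and HDC lower 95% CI bounds of the panel mean;
  prediction HDC iff panel mean ≥ threshold.
* **Clustering & corridor** — hierarchical clustering on significant
  probes with clade purity/ARI; promoter median β against a reference
  corridor with capture and near-miss summaries and per-promoter CV.

A seeded generator (`cphcap.synthetic`) produces full 450K-like cohorts —
2,676 CpH probes, a 20,000-probe CpG pool, 59 rs probes, 25 discovery lines
with 6 replicate extracts, donor lines, control intensities — with known
ground truth, plus artifact injection (failed probes, sample swaps,
under-converted samples) for testing QC.

## Worked example

```python
from cphcap import GeneratorConfig, generate_cohort
from cphcap.pipeline import RunConfig, run_discovery

cohort = generate_cohort(GeneratorConfig(seed=7))
bundle, model = run_discovery(
    cohort.beta, cohort.detection, cohort.annotation, cohort.sheet,
    controls=cohort.controls, donor_map=cohort.truth.donor_map,
    config=RunConfig(seed=7, permutation_B=5000, montecarlo_B=2000))
```

prints (via `examples/07_full_pipeline.py`):

```
delta beta_mean: 14.2 pp (CI 11.6-16.8)
MVPs: 2676 significant, 2676 hyper
permutation p: 2.00e-04; CpG null max |delta|: 0.00055
threshold: 0.474; discovery accuracy: 100%
clustering agreement at k=3: 100%
replication: 9/10 lines correct
```

Reading this: the pipeline recovered a 14.2-percentage-point deficit in mean
CpH methylation in LDC lines (the generator plants 13 ± cohort noise); every
CpH probe is a significant hyper-MVP in HDC; label permutation puts the
contrast at the resolution limit of 5,000 draws while CpG probe subsets
never produce a difference above 0.0006 (the signal is specific to non-CG
context); and the CI-midpoint classifier transfers to a fresh 10-line
replication cohort at 9/10.

The `examples/` directory has one short script per capability (simulation,
QC and artifact recovery, MVP calling, resampling nulls, the classifier,
clustering/corridor, the full pipeline). A thin CLI mirrors the pipeline:
`cphcap simulate|qc|mvp|resample|classify|cluster|corridor|run-discovery|run-replication`.

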