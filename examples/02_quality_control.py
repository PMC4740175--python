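"""Plant QC artifacts in a cohort and watch each QC stage recover them.

Three artifact classes: probes failing detection, a swapped DNA extract
(caught by rs genotype distances), and an under-converted bisulfite sample
(caught by the conversion-efficiency control-probe statistic).
"""

from cphcap import ArtifactSpec, GeneratorConfig, generate_cohort, inject_artifacts
from cphcap.qc import conversion_efficiency_table, filter_detection, flag_replicate_outliers

cohort = generate_cohort(GeneratorConfig(
    seed=5, n_cph=300, n_cpg=500, n_rs=30, n_hdc_lines=4, n_ldc_lines=3,
    n_donor_lines=2, extracts_per_line=3))
tainted = inject_artifacts(
    cohort,
    ArtifactSpec(n_failed_probes=8, n_outlier_extracts=1,
                 n_underconverted_samples=1, underconversion_rate=0.9),
    seed=11)

_, excluded = filter_detection(tainted.beta, tainted.detection)
print(f"detection filter excluded {len(excluded)} probes "
      f"(planted: {len(tainted.truth.failed_probes)}); "
      f"exact match: {sorted(excluded) == sorted(tainted.truth.failed_probes)}")

rs = tainted.beta.subset_probes(tainted.annotation.of_context("rs"))
flagged, _ = flag_replicate_outliers(rs, tainted.sheet)
print(f"flagged extracts: {flagged} (planted: {tainted.truth.outlier_extracts})")

eff = conversion_efficiency_table(tainted.controls)
bad = list(tainted.truth.underconverted_samples)[0]
print(f"conversion efficiency of under-converted sample: {eff[bad]:.1f}% "
      f"(cohort median {eff.median():.1f}%)")
# An efficiency near 90% against a ~99.5% cohort flags the sample whose
# unconverted cytosines would otherwise masquerade as methylation.
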