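"""One-call discovery run + replication with a frozen model.

`run_discovery` chains QC -> replicate averaging -> MVP calling -> group
contrast -> resampling nulls -> panel/threshold -> clustering (-> corridor
when a table is supplied) and returns a validated report bundle plus the
trained classifier. The same flow is available from the shell:

    cphcap simulate --seed 7 --out cohort/
    cphcap run-discovery --beta cohort/beta.tsv --detp cohort/detection.tsv \
        --annotation cohort/annotation.tsv --sheet cohort/samples.csv \
        --controls cohort/controls.tsv --seed 7 --out results/
"""

from cphcap import GeneratorConfig, generate_cohort, generate_replication_cohort
from cphcap.pipeline import RunConfig, run_discovery, run_replication

cohort = generate_cohort(GeneratorConfig(seed=7))
bundle, model = run_discovery(
    cohort.beta, cohort.detection, cohort.annotation, cohort.sheet,
    controls=cohort.controls, donor_map=cohort.truth.donor_map,
    config=RunConfig(seed=7, permutation_B=5000, montecarlo_B=2000))
bundle.validate()

print(f"delta beta_mean: {bundle.delta['delta_beta_mean'] * 100:.1f} pp "
      f"(CI {bundle.delta['ci95'][0] * 100:.1f}-{bundle.delta['ci95'][1] * 100:.1f})")
print(f"MVPs: {bundle.mvp['n_significant']} significant, "
      f"{bundle.mvp['n_hyper']} hyper")
print(f"permutation p: {bundle.resampling['permutation']['p_empirical']:.2e}; "
      f"CpG null max |delta|: {bundle.resampling['montecarlo']['max_abs_null']:.5f}")
print(f"threshold: {bundle.classifier['threshold']:.3f}; "
      f"discovery accuracy: {bundle.evaluation['accuracy']:.0%}")
print(f"clustering agreement at k=3: {bundle.clustering['agreement']:.0%}")

rep = generate_replication_cohort(cohort.truth, seed=41)
rep_bundle = run_replication(model, rep.beta, sheet=rep.sheet)
print(f"replication: {rep_bundle.evaluation['n_correct']}/"
      f"{rep_bundle.evaluation['n']} lines correct")
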