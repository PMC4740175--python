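"""Train the nine-probe biomarker and predict capacity for new lines.

The panel is drawn from the top MVPs; the decision threshold is the midpoint
between the LDC upper and HDC lower 95% CI bounds of the panel mean. A fresh
replication cohort (new lines, same probes) is then classified blind.
"""

from cphcap import GeneratorConfig, generate_cohort, generate_replication_cohort
from cphcap.classifier import derive_threshold, evaluate, predict_capacity, select_panel
from cphcap.mvp import beta_to_m, call_mvps, fit_moderated_t
from cphcap.qc import average_replicates, run_qc

cohort = generate_cohort(GeneratorConfig(seed=7))
beta_qc, sheet_qc, _ = run_qc(cohort.beta, cohort.detection, cohort.annotation,
                              cohort.sheet, controls=cohort.controls)
lines = average_replicates(beta_qc, sheet_qc)
groups = sheet_qc.group_of_line().to_dict()
cph = cohort.annotation.of_context("CpH")
hip = [l for l, g in groups.items() if g in ("HDC", "LDC")]
cph_lines = lines.values.loc[cph, hip]

table = call_mvps(fit_moderated_t(beta_to_m(cph_lines), groups, beta=cph_lines))
panel = select_panel(table, k=9, top=200)
model = derive_threshold(cph_lines, panel, groups)
print(f"panel: {panel}")
print(f"LDC CI ({model.ldc_ci[0]:.3f}, {model.ldc_ci[1]:.3f}); "
      f"HDC CI ({model.hdc_ci[0]:.3f}, {model.hdc_ci[1]:.3f})")
print(f"threshold = {model.threshold:.3f} (CI overlap: {model.ci_overlap})")

rep = generate_replication_cohort(cohort.truth, seed=99)
rep_lines = average_replicates(rep.beta, rep.sheet)
preds = predict_capacity(rep_lines.values.loc[cph], model,
                         true_groups=rep.sheet.group_of_line().to_dict())
print(preds[["panel_mean", "deviation", "predicted", "true"]].round(3))
print(f"replication accuracy: {evaluate(preds)['accuracy']:.0%}")
# Deviations are the signed bars of a threshold plot: positive -> HDC call.
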