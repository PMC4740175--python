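"""One-command discovery and replication runs.

:func:`run_discovery` executes the full discovery workflow in fixed order —
QC -> replicate averaging -> moderated-t MVP calling -> group contrast ->
resampling nulls -> panel + threshold -> prediction -> clustering ->
corridor capture — and returns a :class:`ReportBundle`.  Optional stages
(corridor without a corridor table, memory contrasts without a donor map)
degrade gracefully; required-stage failures abort with a stage-named error
carrying the partial report.

:func:`run_replication` applies a frozen :class:`~cphcap.classifier.ClassifierModel`
to a new beta matrix without retraining.

All randomness is funnelled through per-stage substreams derived from the
single run seed, so toggling one stage never shifts another stage's draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import ClassifierModel, derive_threshold, evaluate, predict_capacity, select_panel
from .clustering import clade_purity, cluster_lines
from .corridor import corridor_capture, map_promoters, promoter_cv, promoter_medians
from .datatypes import (
    BetaMatrix,
    ControlIntensities,
    CorridorTable,
    DetectionMatrix,
    ProbeAnnotation,
    SampleSheet,
    VariantTable,
)
from .mvp import beta_to_m, call_mvps, fit_moderated_t, group_delta, memory_delta, motif_effect_summary
from .qc import average_replicates, run_qc
from .resampling import montecarlo_cpg_null, permutation_test_delta

__all__ = ["RunConfig", "ReportBundle", "StageError", "run_discovery", "run_replication"]

_STAGE_SEED_INDEX = {"qc": 1, "mvp": 2, "resampling": 3, "classifier": 4,
                     "clustering": 5, "corridor": 6}


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    ss = np.random.SeedSequence([int(run_seed), _STAGE_SEED_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Every stage parameter, with the module defaults."""

    detection_alpha: float = 0.01
    min_efficiency: float = 90.0
    svd_k: int = 6
    fdr: float = 0.05
    permutation_B: int = 20000
    montecarlo_B: int = 10000
    mc_beta_min: float = 0.80
    panel_k: int = 9
    panel_top: int = 200
    panel_rule: str = "smallest_p"
    cluster_k: int = 3
    cluster_distance: str = "euclidean"
    cluster_linkage: str = "average"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "qc": True, "mvp": True, "resampling": True, "classifier": True,
        "clustering": True, "corridor": True})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for key, value in d.items():
            if key == "stages":
                cfg.stages.update(value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise KeyError(f"unknown config key {key!r}")
        return cfg


class StageError(RuntimeError):
    """A required pipeline stage failed; carries the partial report."""

    def __init__(self, stage: str, cause: Exception, partial: "ReportBundle"):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial


@dataclass
class ReportBundle:
    """Structured results of a discovery or replication run."""

    config: dict
    seed: int
    version: str = __version__
    qc: dict | None = None
    mvp: dict | None = None
    delta: dict | None = None
    memory: dict | None = None
    motif: list | None = None
    resampling: dict | None = None
    classifier: dict | None = None
    predictions: list | None = None
    evaluation: dict | None = None
    clustering: dict | None = None
    corridor: dict | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items()}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=_jsonify))

    def validate(self) -> None:
        """Check the bundle against the published report schema."""
        from .report_schema import ReportSchema

        ReportSchema.model_validate(json.loads(json.dumps(self.to_dict(),
                                                          default=_jsonify)))
        panel = ((self.classifier or {}).get("panel"))
        if panel and self.mvp is not None and "significant_probes" in (self.mvp or {}):
            sig = set(self.mvp["significant_probes"])
            stray = [p for p in panel if p not in sig]
            if stray:
                raise ValueError(f"panel probes not significant MVPs: {stray}")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    if obj != obj:  # NaN
        return None
    raise TypeError(f"cannot serialise {type(obj)}")


def run_discovery(beta: BetaMatrix, detp: DetectionMatrix,
                  annotation: ProbeAnnotation, sheet: SampleSheet,
                  controls: list[ControlIntensities] | None = None,
                  variants: VariantTable | None = None,
                  corridor: CorridorTable | None = None,
                  donor_map: dict | None = None,
                  config: RunConfig | None = None,
                  ) -> tuple[ReportBundle, ClassifierModel | None]:
    """Full discovery analysis; returns the report and the trained model."""
    cfg = config or RunConfig()
    bundle = ReportBundle(config=asdict(cfg), seed=cfg.seed)
    stages = cfg.stages
    model = None

    # --- QC (required) -----------------------------------------------------
    try:
        beta_qc, sheet_qc, qc_report = run_qc(
            beta, detp, annotation, sheet, controls=controls, variants=variants,
            detection_alpha=cfg.detection_alpha, min_efficiency=cfg.min_efficiency,
            svd_k=cfg.svd_k)
        bundle.qc = qc_report.summary()
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("qc", exc, bundle)
    if not any(stages.get(s) for s in ("mvp", "resampling", "classifier",
                                       "clustering", "corridor")):
        return bundle, None

    line_beta = average_replicates(beta_qc, sheet_qc)
    groups = sheet_qc.group_of_line().to_dict()
    kept_probes = set(line_beta.probe_ids)
    kept_lines = set(line_beta.sample_ids)
    cph_ids = [p for p in annotation.of_context("CpH") if p in kept_probes]
    cpg_ids = [p for p in annotation.of_context("CpG") if p in kept_probes]
    hipsc_lines = [l for l, g in groups.items()
                   if g in ("HDC", "LDC") and l in kept_lines]
    cph_lines = line_beta.values.loc[cph_ids, hipsc_lines]

    mvp_table = None
    if stages.get("mvp", True):
        try:
            m = beta_to_m(cph_lines)
            mvp_table = call_mvps(fit_moderated_t(m, groups, beta=cph_lines),
                                  fdr=cfg.fdr)
            summary = mvp_table.summary()
            summary["significant_probes"] = mvp_table.significant_probes
            bundle.mvp = summary
            delta = group_delta(cph_lines, groups)
            bundle.delta = delta.summary()
            if donor_map:
                donor_cols = [l for l in line_beta.sample_ids
                              if groups.get(l) == "donor" or l in hipsc_lines]
                pairs, mem_summary, donor_res, skipped = memory_delta(
                    line_beta.values.loc[cph_ids, donor_cols], donor_map, groups)
                bundle.memory = {
                    "pairs": pairs.to_dict(orient="records"),
                    "group_mean_delta": mem_summary,
                    "donor_vs_donor": None if donor_res is None else donor_res.summary(),
                    "skipped_lines": skipped,
                }
            motif = motif_effect_summary(mvp_table, annotation)
            bundle.motif = motif.reset_index().to_dict(orient="records")
        except Exception as exc:
            raise StageError("mvp", exc, bundle)

    if stages.get("resampling", True):
        try:
            perm = permutation_test_delta(
                cph_lines, groups, B=cfg.permutation_B,
                seed=stage_seed(cfg.seed, "resampling"))
            res = {"permutation": perm.summary()}
            cpg_lines = line_beta.values.loc[cpg_ids, hipsc_lines]
            if len(cpg_ids) >= len(cph_ids):
                mc = montecarlo_cpg_null(
                    cpg_lines, groups, n_probes=len(cph_ids), B=cfg.montecarlo_B,
                    seed=stage_seed(cfg.seed, "resampling") + 1)
                res["montecarlo"] = mc.summary()
                try:
                    mc_meth = montecarlo_cpg_null(
                        cpg_lines, groups, n_probes=len(cph_ids),
                        B=cfg.montecarlo_B, beta_min=cfg.mc_beta_min,
                        seed=stage_seed(cfg.seed, "resampling") + 2)
                    res["montecarlo_methylated"] = mc_meth.summary()
                except ValueError:
                    res["montecarlo_methylated"] = None
            bundle.resampling = res
        except Exception as exc:
            raise StageError("resampling", exc, bundle)

    if stages.get("classifier", True) and mvp_table is not None:
        try:
            panel = select_panel(mvp_table, k=cfg.panel_k, top=cfg.panel_top,
                                 rule=cfg.panel_rule,
                                 seed=stage_seed(cfg.seed, "classifier"))
            model = derive_threshold(
                cph_lines, panel, groups,
                provenance={"cohort": "discovery", "fdr": cfg.fdr,
                            "rule": cfg.panel_rule, "top": cfg.panel_top})
            bundle.classifier = model.summary()
            preds = predict_capacity(cph_lines, model, true_groups=groups)
            bundle.predictions = preds.reset_index().to_dict(orient="records")
            bundle.evaluation = evaluate(preds)
        except Exception as exc:
            raise StageError("classifier", exc, bundle)

    if stages.get("clustering", True) and mvp_table is not None:
        try:
            sig = mvp_table.significant_probes
            all_lines = [l for l in line_beta.sample_ids]
            result = cluster_lines(line_beta.values.loc[:, all_lines], sig,
                                   distance=cfg.cluster_distance,
                                   method=cfg.cluster_linkage)
            purity = clade_purity(result, groups, k=cfg.cluster_k)
            bundle.clustering = {**result.summary(), **purity}
        except Exception as exc:
            raise StageError("clustering", exc, bundle)

    if stages.get("corridor", True) and corridor is not None:
        try:
            mapping = map_promoters(annotation, corridor)
            stem_lines = [l for l in line_beta.sample_ids
                          if groups.get(l) in ("HDC", "LDC")]
            medians = promoter_medians(line_beta.values[stem_lines], mapping)
            capture = corridor_capture(medians, corridor)
            cv = promoter_cv(medians)
            bundle.corridor = {
                "n_promoters_mapped": len(mapping),
                "capture_fraction": capture["capture_fraction"],
                "n_estimates": capture["n_estimates"],
                "near_miss_fraction": capture["near_miss_fraction"],
                "far_miss_fraction": capture["far_miss_fraction"],
                "n_zero_capture_promoters": len(capture["zero_capture_promoters"]),
                "mean_cv": float(cv.mean(skipna=True)),
                "max_cv": float(cv.max(skipna=True)),
            }
        except Exception as exc:
            raise StageError("corridor", exc, bundle)

    return bundle, model


def run_replication(model: ClassifierModel, beta: BetaMatrix,
                    sheet: SampleSheet | None = None,
                    true_groups: dict | None = None,
                    config: RunConfig | None = None) -> ReportBundle:
    """Predict capacity for new lines with a frozen model (no retraining)."""
    cfg = config or RunConfig()
    bundle = ReportBundle(config=asdict(cfg), seed=cfg.seed)
    if sheet is not None:
        line_beta = average_replicates(beta, sheet)
        if true_groups is None:
            true_groups = sheet.group_of_line().to_dict()
    else:
        line_beta = beta
    preds = predict_capacity(line_beta, model, true_groups=true_groups)
    bundle.classifier = model.summary()
    bundle.predictions = preds.reset_index().to_dict(orient="records")
    bundle.evaluation = evaluate(preds)
    return bundle
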