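"""Nine-probe non-CG biomarker: panel selection, threshold, prediction.

The biomarker condenses the differential non-CG signal into a small panel
(default 9 probes chosen from the top 200 MVPs).  On the discovery cohort,
each line is reduced to its mean beta over the panel; per phenotype group a
t-based 95% CI of that mean is computed, and the decision threshold is the
midpoint between the upper CI bound of the low-capacity (LDC) group and the
lower CI bound of the high-capacity (HDC) group.  A new line is predicted
HDC when its panel mean is at or above the threshold (ties go to HDC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import BetaMatrix
from .mvp import MVPTable, _group_ci

__all__ = [
    "ClassifierModel",
    "select_panel",
    "derive_threshold",
    "predict_capacity",
    "evaluate",
]


@dataclass
class ClassifierModel:
    """Frozen panel + group CIs + midpoint threshold."""

    panel: list[str]
    ldc_ci: tuple[float, float]
    hdc_ci: tuple[float, float]
    threshold: float
    ldc_mean: float
    hdc_mean: float
    ci_overlap: bool
    provenance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "panel": self.panel,
            "ldc_ci": list(self.ldc_ci),
            "hdc_ci": list(self.hdc_ci),
            "threshold": self.threshold,
            "ldc_mean": self.ldc_mean,
            "hdc_mean": self.hdc_mean,
            "ci_overlap": self.ci_overlap,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(panel=list(d["panel"]), ldc_ci=tuple(d["ldc_ci"]),
                   hdc_ci=tuple(d["hdc_ci"]), threshold=float(d["threshold"]),
                   ldc_mean=float(d["ldc_mean"]), hdc_mean=float(d["hdc_mean"]),
                   ci_overlap=bool(d["ci_overlap"]),
                   provenance=dict(d.get("provenance", {})))

    def summary(self) -> dict:
        return {
            "panel": self.panel,
            "threshold": float(self.threshold),
            "ldc_ci": [float(v) for v in self.ldc_ci],
            "hdc_ci": [float(v) for v in self.hdc_ci],
            "ci_overlap": self.ci_overlap,
        }


def select_panel(table: MVPTable, k: int = 9, top: int = 200,
                 rule: str = "smallest_p", seed: int | None = None) -> list[str]:
    """Choose a k-probe panel from the top MVPs.

    Significant MVPs are ranked by p ascending; the pool is the ``top``
    best. Rules: ``smallest_p`` (default) takes the k smallest-p probes;
    ``spread`` greedily picks k probes maximising the minimum pairwise
    |delta-beta| distance within the pool (deterministic given the seeded
    start probe). The study's own criterion for its panel (assayability on
    a secondary platform) is not computable from array data.
    """
    sig = table.frame[table.frame.get("significant", pd.Series(True, index=table.frame.index))]
    sig = sig.sort_values("p", kind="mergesort")
    pool = sig.head(top)
    if k > len(pool):
        raise ValueError(f"k={k} exceeds MVP pool of {len(pool)}")
    if rule == "smallest_p":
        return list(pool.index[:k])
    if rule == "spread":
        vals = pool["delta_beta"].to_numpy()[:, None]
        dmat = squareform(pdist(vals))
        rng = np.random.default_rng(seed)
        chosen = [int(rng.integers(len(pool)))]
        while len(chosen) < k:
            mind = dmat[:, chosen].min(axis=1)
            mind[chosen] = -1.0
            chosen.append(int(np.argmax(mind)))
        return [pool.index[i] for i in sorted(chosen)]
    raise ValueError(f"unknown selection rule {rule!r}")


def _panel_means(line_beta, panel: list[str], max_missing_frac: float = 1 / 3):
    frame = line_beta.values if isinstance(line_beta, BetaMatrix) else line_beta
    missing = [p for p in panel if p not in frame.index]
    if missing:
        raise KeyError(f"panel probes missing from matrix: {missing}")
    sub = frame.loc[panel]
    means = sub.mean(axis=0, skipna=True)
    frac_missing = sub.isna().mean(axis=0)
    means[frac_missing > max_missing_frac] = np.nan
    return means


def derive_threshold(line_beta, panel: list[str], groups: Mapping[str, str],
                     level: float = 0.95, provenance: dict | None = None) -> ClassifierModel:
    """CI-midpoint threshold from line-level panel means on the discovery set.

    threshold = (upper 95% CI bound of the LDC panel mean
                 + lower 95% CI bound of the HDC panel mean) / 2.
    Overlapping CIs still yield a model, with ``ci_overlap`` set.
    """
    means = _panel_means(line_beta, panel)
    hdc = means[[l for l in means.index if groups.get(l) == "HDC"]].dropna()
    ldc = means[[l for l in means.index if groups.get(l) == "LDC"]].dropna()
    if len(hdc) < 2 or len(ldc) < 2:
        raise ValueError("need >= 2 lines per group to derive the threshold")
    hdc_mean, hdc_ci, _ = _group_ci(hdc.to_numpy(), level)
    ldc_mean, ldc_ci, _ = _group_ci(ldc.to_numpy(), level)
    threshold = (ldc_ci[1] + hdc_ci[0]) / 2.0
    return ClassifierModel(
        panel=list(panel), ldc_ci=ldc_ci, hdc_ci=hdc_ci,
        threshold=float(threshold), ldc_mean=ldc_mean, hdc_mean=hdc_mean,
        ci_overlap=bool(ldc_ci[1] > hdc_ci[0]),
        provenance=provenance or {})


def predict_capacity(line_beta, model: ClassifierModel,
                     true_groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Predict HDC/LDC per line from panel mean beta against the threshold.

    Returns one row per line: panel_mean, deviation (panel mean minus
    threshold, the signed bar of a deviation plot), predicted label
    (HDC iff deviation >= 0), and the true label when known. Lines with more
    than a third of panel probes missing are marked unpredictable (NaN).
    """
    means = _panel_means(line_beta, model.panel)
    rows = []
    for line_id, m in means.items():
        if np.isnan(m):
            rows.append({"line_id": line_id, "panel_mean": np.nan,
                         "deviation": np.nan, "predicted": None})
            continue
        dev = float(m - model.threshold)
        rows.append({"line_id": line_id, "panel_mean": float(m),
                     "deviation": dev,
                     "predicted": "HDC" if dev >= 0 else "LDC"})
    out = pd.DataFrame(rows).set_index("line_id")
    if true_groups is not None:
        out["true"] = [true_groups.get(l) for l in out.index]
    return out


def evaluate(predictions: pd.DataFrame) -> dict:
    """Confusion counts and accuracy over lines with known labels."""
    if "true" not in predictions.columns:
        return {"n": 0, "skipped": True}
    labelled = predictions[predictions["true"].isin(["HDC", "LDC"])
                           & predictions["predicted"].notna()]
    if len(labelled) == 0:
        return {"n": 0, "skipped": True}
    confusion = {f"{t}_as_{p}": int(((labelled["true"] == t)
                                     & (labelled["predicted"] == p)).sum())
                 for t in ("HDC", "LDC") for p in ("HDC", "LDC")}
    correct = labelled["true"] == labelled["predicted"]
    return {
        "n": int(len(labelled)),
        "n_correct": int(correct.sum()),
        "accuracy": float(correct.mean()),
        "confusion": confusion,
        "per_line_correct": {l: bool(c) for l, c in correct.items()},
        "skipped": False,
    }
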