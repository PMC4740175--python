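"""Promoter-level comparison against a reference methylation corridor.

A "reference corridor" gives, per promoter, the [lower, upper] range of
methylation observed across reference pluripotent lines.  Probes are mapped
to promoters by genomic overlap (1-based inclusive), promoter methylation is
summarised per sample by the median beta of member probes (robust to single
aberrant probes), and each promoter x sample estimate is scored as captured
when it falls inside the corridor.  Missed estimates are summarised by their
absolute beta distance to the nearest bound (near-miss fractions within 0.10
and 0.20).  Per-promoter coefficients of variation across samples quantify
stability.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, CorridorTable, ProbeAnnotation

__all__ = [
    "map_promoters",
    "promoter_medians",
    "corridor_capture",
    "promoter_cv",
]


def map_promoters(annotation: ProbeAnnotation, corridor: CorridorTable,
                  contexts: Iterable[str] = ("CpG",)) -> dict[str, list[str]]:
    """Map promoters to the probes overlapping them (start <= pos <= end).

    A probe may land in several overlapping promoters; promoters with no
    probe are dropped.
    """
    ann = annotation.frame
    ann = ann[ann["context"].isin(set(contexts))]
    by_chrom = {c: g.sort_values("position") for c, g in ann.groupby("chromosome")}
    mapping: dict[str, list[str]] = {}
    for row in corridor.frame.itertuples(index=False):
        g = by_chrom.get(row.chromosome)
        if g is None:
            continue
        pos = g["position"].to_numpy()
        i = np.searchsorted(pos, int(row.start), side="left")
        j = np.searchsorted(pos, int(row.end), side="right")
        if j > i:
            mapping[row.promoter_id] = list(g["probe_id"].iloc[i:j])
    return mapping


def promoter_medians(beta, mapping: dict[str, list[str]]) -> pd.DataFrame:
    """Promoter x sample matrix of median member-probe beta.

    Missing betas are excluded per cell; a promoter whose members are all
    missing in a sample is missing there.
    """
    frame = beta.values if isinstance(beta, BetaMatrix) else beta
    present = set(frame.index)
    pairs = [(pid, p) for pid, probes in mapping.items()
             for p in probes if p in present]
    if not pairs:
        return pd.DataFrame(columns=frame.columns)
    sub = frame.loc[[p for _, p in pairs]]
    sub.index = pd.Index([pid for pid, _ in pairs], name="promoter_id")
    out = sub.groupby(level=0, sort=False).median()
    order = [pid for pid in mapping if pid in set(out.index)]
    return out.loc[order]


def corridor_capture(medians: pd.DataFrame, corridor: CorridorTable,
                     near: float = 0.10, far: float = 0.20) -> dict:
    """Score promoter x sample estimates against corridor bounds.

    An estimate is captured iff lower <= median <= upper (bounds inclusive).
    For misses, the distance to the nearest bound is computed in absolute
    beta units and binned at ``near`` and ``far``. Promoters absent from the
    corridor are skipped and counted.
    """
    bounds = corridor.frame.set_index("promoter_id")[["lower", "upper"]]
    shared = [p for p in medians.index if p in bounds.index]
    skipped = len(medians.index) - len(shared)
    sub = medians.loc[shared]
    lo = bounds.loc[shared, "lower"].to_numpy()[:, None]
    up = bounds.loc[shared, "upper"].to_numpy()[:, None]
    vals = sub.to_numpy(dtype=float)
    present = ~np.isnan(vals)
    captured = (vals >= lo) & (vals <= up) & present

    n_est = int(present.sum())
    n_cap = int(captured.sum())
    missed = present & ~captured
    dist = np.where(vals < lo, lo - vals, np.where(vals > up, vals - up, 0.0))
    miss_d = dist[missed]
    per_prom = captured.sum(axis=1)
    zero_capture = [shared[i] for i in range(len(shared))
                    if per_prom[i] == 0 and present[i].any()]
    return {
        "n_estimates": n_est,
        "n_captured": n_cap,
        "capture_fraction": (n_cap / n_est) if n_est else np.nan,
        "per_promoter_captured": pd.Series(per_prom, index=shared),
        "zero_capture_promoters": zero_capture,
        "n_missed": int(missed.sum()),
        "near_miss_fraction": (float((miss_d <= near).mean()) if miss_d.size else np.nan),
        "far_miss_fraction": (float((miss_d <= far).mean()) if miss_d.size else np.nan),
        "n_skipped_promoters": skipped,
    }


def promoter_cv(medians: pd.DataFrame) -> pd.Series:
    """Coefficient of variation (sample sd / mean) per promoter across samples.

    Promoters with fewer than two non-missing samples, or mean zero, give
    missing CV.
    """
    means = medians.mean(axis=1, skipna=True)
    sds = medians.std(axis=1, ddof=1, skipna=True)
    counts = medians.notna().sum(axis=1)
    cv = sds / means
    cv[(counts < 2) | (means == 0)] = np.nan
    cv.name = "cv"
    return cv
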