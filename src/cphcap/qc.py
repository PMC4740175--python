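"""Sample- and probe-level quality control.

Stages, in the order the discovery pipeline applies them:

1. :func:`conversion_efficiency` — per-sample bisulfite conversion efficiency
   from Infinium-I conversion-control intensities: subtract the mean
   negative-control intensity from each of the 3 converted (BIC) and 3
   unconverted (BIU) control intensities, floor at zero, and report
   ``100 * sum(adj BIC) / (sum(adj BIC) + sum(adj BIU))``.
2. :func:`filter_detection` — drop probes whose detection p exceeds alpha in
   at least one DNA extract (the measurement never rose above background).
3. :func:`flag_replicate_outliers` — identity check on rs genotyping probes:
   an extract whose nearest neighbour (Euclidean distance on rs betas)
   belongs to a different cell line is flagged as a likely sample swap.
4. :func:`average_replicates` — collapse extracts to one column per line.
5. :func:`filter_probes` — exclude sex-chromosome probes; flag probes with a
   known variant at the target dinucleotide or within 10 bp on the
   single-base-extension side.
6. :func:`svd_confounder_scan` — associate top right-singular vectors of the
   row-centred beta matrix with batch/phenotype covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    BetaMatrix,
    ControlIntensities,
    DetectionMatrix,
    ProbeAnnotation,
    SampleSheet,
    VariantTable,
)

__all__ = [
    "QcReport",
    "conversion_efficiency",
    "conversion_efficiency_table",
    "filter_detection",
    "flag_replicate_outliers",
    "average_replicates",
    "filter_probes",
    "svd_confounder_scan",
    "run_qc",
]

REASON_DETECTION = "detection_fail"
REASON_SEX = "sex_chromosome"
REASON_VARIANT_TARGET = "variant_at_target"
REASON_VARIANT_3PRIME = "variant_3prime_10bp"


@dataclass
class QcReport:
    """Everything the QC stage decided, with reasons."""

    conversion_efficiency: dict[str, float | None] = field(default_factory=dict)
    excluded_probes: dict[str, str] = field(default_factory=dict)   # probe -> primary reason
    flagged_probes: dict[str, list[str]] = field(default_factory=dict)  # advisory flags
    outlier_extracts: list[str] = field(default_factory=list)
    skipped_single_extract_lines: list[str] = field(default_factory=list)
    svd_associations: pd.DataFrame | None = None
    low_efficiency_samples: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        eff = {k: (None if v is None else round(float(v), 3))
               for k, v in self.conversion_efficiency.items()}
        reason_counts: dict[str, int] = {}
        for reason in self.excluded_probes.values():
            reason_counts[reason] = reason_counts.get(reason, 0) + 1
        return {
            "conversion_efficiency": eff,
            "n_excluded_probes": len(self.excluded_probes),
            "excluded_by_reason": reason_counts,
            "n_flagged_probes": len(self.flagged_probes),
            "outlier_extracts": list(self.outlier_extracts),
            "low_efficiency_samples": list(self.low_efficiency_samples),
            "svd_associations": (None if self.svd_associations is None
                                 else self.svd_associations.round(6).to_dict()),
        }


def conversion_efficiency(ci: ControlIntensities) -> float | None:
    """Bisulfite conversion efficiency in percent for one sample.

    Returns None (degenerate controls) when both background-adjusted sums
    are zero; scale-invariant in the raw intensities.
    """
    background = float(np.mean(ci.negatives))
    adj_c = np.maximum(ci.bic - background, 0.0)
    adj_u = np.maximum(ci.biu - background, 0.0)
    num = float(adj_c.sum())
    den = float(adj_c.sum() + adj_u.sum())
    if den == 0.0:
        return None
    # divide before scaling so num == den gives exactly 100.0
    return min(100.0, 100.0 * (num / den))


def conversion_efficiency_table(controls: list[ControlIntensities]) -> pd.Series:
    return pd.Series({ci.sample_id: conversion_efficiency(ci) for ci in controls},
                     dtype=float)


def filter_detection(beta: BetaMatrix, detp: DetectionMatrix,
                     alpha: float = 0.01) -> tuple[BetaMatrix, list[str]]:
    """Exclude probes failing detection (p > alpha) in >= 1 extract."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} must be in (0, 1)")
    aligned = detp.values.reindex(index=beta.probe_ids, columns=beta.sample_ids)
    failed = aligned.gt(alpha).any(axis=1)
    excluded = list(aligned.index[failed])
    kept = beta.values.loc[~failed.to_numpy()]
    return BetaMatrix(kept), excluded


def flag_replicate_outliers(rs_beta: BetaMatrix,
                            sheet: SampleSheet) -> tuple[list[str], list[str]]:
    """Flag extracts whose rs genotype profile sits closer to another line.

    For each extract, Euclidean distance on rs-probe beta is computed to its
    own line's centroid (excluding the extract itself) and to every other
    line's centroid; the extract is flagged when some other line is strictly
    closer. A deterministic surrogate for spotting mislabelled/swapped
    extracts on a replicate-distance plot; leaving the extract itself out of
    its own centroid keeps a swap from masking itself, and using centroids
    keeps the swap from dragging its source line's genuine extracts into
    false flags. Returns ``(flagged_extracts, skipped_lines)``; lines with a
    single extract cannot be checked and are reported as skipped.
    """
    line_of = sheet.line_of()
    samples = [s for s in rs_beta.sample_ids if s in line_of.index]
    counts = line_of.loc[samples].value_counts()
    skipped = sorted(counts.index[counts < 2])
    checkable = [s for s in samples if counts[line_of[s]] >= 2]
    if len(checkable) < 2 or counts.size < 2:
        return [], skipped

    x = rs_beta.values[samples].to_numpy().T  # extracts x rs probes
    lines = list(dict.fromkeys(line_of.loc[samples]))
    sums = {l: x[[i for i, s in enumerate(samples) if line_of[s] == l]].sum(axis=0)
            for l in lines}
    flagged = []
    for i, s in enumerate(checkable):
        own = line_of[s]
        j = samples.index(s)
        own_centroid = (sums[own] - x[j]) / (counts[own] - 1)
        d_own = float(np.linalg.norm(x[j] - own_centroid))
        d_other = min(float(np.linalg.norm(x[j] - sums[l] / counts[l]))
                      for l in lines if l != own)
        if d_other < d_own:
            flagged.append(s)
    return flagged, skipped


def average_replicates(beta: BetaMatrix, sheet: SampleSheet) -> BetaMatrix:
    """Average extracts to one column per line (pairwise-complete means).

    Lines retain the sample-sheet order; a line whose extracts are all
    absent from the matrix is dropped.
    """
    line_of = sheet.line_of()
    present = [s for s in beta.sample_ids if s in line_of.index]
    cols = {}
    for line_id in dict.fromkeys(line_of.loc[present]):
        extracts = [s for s in present if line_of[s] == line_id]
        cols[line_id] = beta.values[extracts].mean(axis=1, skipna=True)
    return BetaMatrix(pd.DataFrame(cols, index=beta.probe_ids))


def _variant_flags(annotation: ProbeAnnotation, variants: VariantTable) -> dict[str, list[str]]:
    """Advisory variant flags per probe.

    ``variant_at_target``: a variant at the target dinucleotide (positions
    p, p+1 on the probe strand, p-1, p for minus-strand probes).
    ``variant_3prime_10bp``: a variant within the 10 bases adjacent to the
    target on the single-base-extension side (downstream of the target in
    probe orientation) — an approximation of the 3' end of the probe.
    """
    flags: dict[str, list[str]] = {}
    if len(variants.frame) == 0:
        return flags
    by_chrom = {c: np.sort(g["position"].to_numpy())
                for c, g in variants.frame.groupby("chromosome")}
    for row in annotation.frame.itertuples(index=False):
        pos_list = by_chrom.get(row.chromosome)
        if pos_list is None:
            continue
        p = int(row.position)
        if row.strand == "+":
            target = (p, p + 1)
            window = (p + 2, p + 11)
        else:
            target = (p - 1, p)
            window = (p - 11, p - 2)

        def any_in(lo: int, hi: int) -> bool:
            i = np.searchsorted(pos_list, lo, side="left")
            return i < len(pos_list) and pos_list[i] <= hi

        probe_flags = []
        if any_in(*target):
            probe_flags.append(REASON_VARIANT_TARGET)
        if any_in(*window):
            probe_flags.append(REASON_VARIANT_3PRIME)
        if probe_flags:
            flags[row.probe_id] = probe_flags
    return flags


def filter_probes(annotation: ProbeAnnotation,
                  variants: VariantTable | None = None,
                  sex_chroms: tuple[str, ...] = ("chrX", "chrY", "X", "Y"),
                  ) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Sex-chromosome exclusions plus advisory variant flags.

    Returns ``(excluded, flagged)`` where ``excluded`` maps probe -> primary
    reason (sex_chromosome) and ``flagged`` maps probe -> variant flags.
    Variant hits are reported, not excluded (they quantify potential
    confounding rather than invalidate the measurement).
    """
    excluded = {
        row.probe_id: REASON_SEX
        for row in annotation.frame.itertuples(index=False)
        if row.chromosome in sex_chroms
    }
    flagged = _variant_flags(annotation, variants) if variants is not None else {}
    return excluded, flagged


def svd_confounder_scan(beta: BetaMatrix, sheet: SampleSheet, k: int = 6,
                        covariates: list[str] | None = None) -> pd.DataFrame:
    """Associate the top-k sample-space singular vectors with covariates.

    The probe x sample matrix is centred per probe; right-singular vectors
    index samples. Categorical covariates use Kruskal-Wallis, numeric ones a
    Pearson correlation test. Constant covariates get NaN.
    """
    if covariates is None:
        covariates = ["group", "cell_class", "batch", "slide", "array_position",
                      "sex", "passage"]
    samples = list(beta.sample_ids)
    if k > len(samples):
        raise ValueError(f"k={k} exceeds number of samples ({len(samples)})")
    x = beta.values.to_numpy(dtype=float)
    x = np.where(np.isnan(x), np.nanmean(x, axis=1, keepdims=True), x)
    x = x - x.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    components = vt[:k]  # k x samples

    meta = sheet.frame.set_index("sample_id").loc[samples]
    out = {}
    for cov in covariates:
        if cov not in meta.columns:
            continue
        values = meta[cov]
        pvals = []
        for comp in components:
            if pd.api.types.is_numeric_dtype(values):
                mask = values.notna().to_numpy()
                if mask.sum() < 3 or values[mask].nunique() < 2:
                    pvals.append(np.nan)
                    continue
                _, p = stats.pearsonr(comp[mask], values[mask].to_numpy(dtype=float))
            else:
                groups = [comp[(values == lvl).to_numpy()] for lvl in values.dropna().unique()]
                groups = [g for g in groups if len(g)]
                if len(groups) < 2:
                    pvals.append(np.nan)
                    continue
                _, p = stats.kruskal(*groups)
            pvals.append(float(p))
        out[cov] = pvals
    return pd.DataFrame(out, index=[f"PC{i + 1}" for i in range(k)])


def run_qc(beta: BetaMatrix, detp: DetectionMatrix, annotation: ProbeAnnotation,
           sheet: SampleSheet, controls: list[ControlIntensities] | None = None,
           variants: VariantTable | None = None, detection_alpha: float = 0.01,
           min_efficiency: float = 90.0, svd_k: int = 6,
           ) -> tuple[BetaMatrix, SampleSheet, QcReport]:
    """Full QC pass returning the filtered extract-level matrix and report.

    Order: conversion efficiency (drop samples below ``min_efficiency``),
    detection filtering, rs outlier flagging (flagged extracts dropped),
    sex-chromosome probe exclusion, SVD confounder scan.
    """
    report = QcReport()

    if controls is not None:
        eff = conversion_efficiency_table(controls)
        report.conversion_efficiency = eff.to_dict()
        present = set(beta.sample_ids)
        bad = [s for s, v in eff.items()
               if s in present and (pd.isna(v) or v < min_efficiency)]
        report.low_efficiency_samples = bad
        if bad:
            bad_set = set(bad)
            beta = beta.subset_samples([s for s in beta.sample_ids if s not in bad_set])

    beta, detect_excluded = filter_detection(beta, detp, alpha=detection_alpha)
    for p in detect_excluded:
        report.excluded_probes[p] = REASON_DETECTION

    rs_ids = annotation.of_context("rs")
    kept_probes = set(beta.probe_ids)
    rs_present = [p for p in rs_ids if p in kept_probes]
    if rs_present:
        flagged, skipped = flag_replicate_outliers(beta.subset_probes(rs_present), sheet)
        report.outlier_extracts = flagged
        report.skipped_single_extract_lines = skipped
        if flagged:
            flagged_set = set(flagged)
            beta = beta.subset_samples([s for s in beta.sample_ids
                                        if s not in flagged_set])

    sex_excluded, flagged_probes = filter_probes(annotation, variants)
    report.flagged_probes = flagged_probes
    sex_hit = [p for p in beta.probe_ids if p in sex_excluded]
    for p in sex_hit:
        report.excluded_probes[p] = REASON_SEX
    if sex_hit:
        sex_set = set(sex_hit)
        beta = beta.subset_probes([p for p in beta.probe_ids if p not in sex_set])

    if beta.shape[1] >= svd_k:
        report.svd_associations = svd_confounder_scan(beta, sheet, k=svd_k)

    sheet_out = sheet.subset(beta.sample_ids)
    return beta, sheet_out, report
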