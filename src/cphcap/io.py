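"""Readers and writers for the package's plain-text interchange formats.

Formats (all headered, tab-separated unless noted):

* beta / detection matrix — first column ``probe_id``, one column per sample;
  missing beta written as ``NA``.
* probe annotation — ``probe_id  context  chromosome  position  strand  flank6``.
* sample sheet — CSV with the :data:`~cphcap.datatypes.SHEET_COLUMNS` columns.
* control intensities — long TSV ``sample_id  kind  index  intensity`` with
  kind in {bic, biu, negative}.
* corridor — ``promoter_id  chromosome  start  end  lower  upper``.
* variants — ``chromosome  position  ref  alt``; a VCF 4.x body (## headers,
  #CHROM line) is also accepted, using its first five columns.

Floats are written with 6 decimals so write->read is the identity at that
precision; reads are validated and never silently drop rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    SHEET_COLUMNS,
    BetaMatrix,
    ControlIntensities,
    CorridorTable,
    DetectionMatrix,
    FormatError,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
    VariantTable,
)

__all__ = [
    "ValidationReport",
    "read_beta_dataset",
    "read_beta_matrix",
    "read_detection_matrix",
    "read_annotation",
    "read_sample_sheet",
    "read_control_intensities",
    "read_corridor",
    "read_variants",
    "write_beta_matrix",
    "write_annotation",
    "write_sample_sheet",
    "write_control_intensities",
    "write_tables",
    "load_config",
]

FLOAT_FMT = "%.6f"


@dataclass
class ValidationReport:
    """Record of records dropped or reordered while aligning a dataset."""

    messages: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.messages.append(msg)

    @property
    def empty(self) -> bool:
        return not self.messages


def read_beta_matrix(path) -> BetaMatrix:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    if frame.columns[0] != "probe_id":
        raise FormatError(f"{path}: first column must be 'probe_id'")
    frame = frame.set_index("probe_id")
    return BetaMatrix(frame)


def read_detection_matrix(path) -> DetectionMatrix:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    if frame.columns[0] != "probe_id":
        raise FormatError(f"{path}: first column must be 'probe_id'")
    return DetectionMatrix(frame.set_index("probe_id"))


def read_annotation(path) -> ProbeAnnotation:
    frame = pd.read_csv(path, sep="\t", dtype={"flank6": str}, keep_default_na=False,
                        na_values=[])
    frame["position"] = frame["position"].astype(int)
    return ProbeAnnotation(frame)


def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    # passage is the only numeric field; keep others as strings
    if "passage" in frame.columns:
        frame["passage"] = pd.to_numeric(frame["passage"], errors="coerce")
    return SampleSheet(frame)


def read_beta_dataset(beta_path, annotation_path, sheet_path):
    """Read and align a beta matrix with its annotation and sample sheet.

    Returns ``(BetaMatrix, ProbeAnnotation, SampleSheet, ValidationReport)``.
    Probes are reordered to annotation order and samples to sheet order
    (the canonical orders). A sample present in the matrix but absent from
    the sheet is an error; annotation rows without matrix data are dropped
    into the report.
    """
    beta = read_beta_matrix(beta_path)
    annotation = read_annotation(annotation_path)
    sheet = read_sample_sheet(sheet_path)
    report = ValidationReport()

    sheet_sample_set = set(sheet.sample_ids)
    missing_samples = [s for s in beta.sample_ids if s not in sheet_sample_set]
    if missing_samples:
        raise ValidationError(
            f"samples in beta matrix absent from sample sheet: {missing_samples}"
        )

    beta_probe_set = set(beta.probe_ids)
    ann_probes = [p for p in annotation.probe_ids if p in beta_probe_set]
    dropped_ann = [p for p in annotation.probe_ids if p not in beta_probe_set]
    for p in dropped_ann:
        report.add(f"annotation probe {p!r} has no beta data; dropped")
    ann_probe_set = set(annotation.probe_ids)
    stray = [p for p in beta.probe_ids if p not in ann_probe_set]
    for p in stray:
        report.add(f"beta probe {p!r} has no annotation; dropped")

    beta_sample_set = set(beta.sample_ids)
    sheet_samples = [s for s in sheet.sample_ids if s in beta_sample_set]
    extra_sheet = [s for s in sheet.sample_ids if s not in beta_sample_set]
    for s in extra_sheet:
        report.add(f"sheet sample {s!r} has no beta data; kept in sheet only")

    beta = BetaMatrix(beta.values.loc[ann_probes, sheet_samples])
    annotation = annotation.subset(ann_probes)
    return beta, annotation, sheet, report


def read_control_intensities(path) -> list[ControlIntensities]:
    frame = pd.read_csv(path, sep="\t")
    need = {"sample_id", "kind", "index", "intensity"}
    if not need.issubset(frame.columns):
        raise FormatError(f"{path}: control table needs columns {sorted(need)}")
    out = []
    for sample_id, grp in frame.groupby("sample_id", sort=False):
        bic = grp[grp["kind"] == "bic"].sort_values("index")["intensity"].to_numpy()
        biu = grp[grp["kind"] == "biu"].sort_values("index")["intensity"].to_numpy()
        neg = grp[grp["kind"] == "negative"].sort_values("index")["intensity"].to_numpy()
        out.append(ControlIntensities(str(sample_id), bic, biu, neg))
    return out


def read_corridor(path) -> CorridorTable:
    frame = pd.read_csv(path, sep="\t")
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    return CorridorTable(frame)


def read_variants(path) -> VariantTable:
    """Read a variant table; plain TSV or a VCF 4.x body (first 5 columns)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##") or first.startswith("#CHROM"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    raise FormatError(f"{path}: VCF body row with <5 columns")
                rows.append((parts[0], int(parts[1]), parts[3], parts[4]))
        frame = pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt"])
    else:
        frame = pd.read_csv(path, sep="\t")
        frame["position"] = frame["position"].astype(int)
    return VariantTable(frame)


def _write_float_frame(frame: pd.DataFrame, path, index_label: str) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, na_rep="NA",
                 index_label=index_label)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    _write_float_frame(beta.values, path, "probe_id")


def write_detection_matrix(detp: DetectionMatrix, path) -> None:
    _write_float_frame(detp.values, path, "probe_id")


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.frame.to_csv(path, sep="\t", index=False)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, columns=SHEET_COLUMNS, index=False)


def write_control_intensities(controls: list[ControlIntensities], path) -> None:
    rows = []
    for ci in controls:
        rows.extend((ci.sample_id, "bic", i + 1, v) for i, v in enumerate(ci.bic))
        rows.extend((ci.sample_id, "biu", i + 1, v) for i, v in enumerate(ci.biu))
        rows.extend((ci.sample_id, "negative", i + 1, v) for i, v in enumerate(ci.negatives))
    frame = pd.DataFrame(rows, columns=["sample_id", "kind", "index", "intensity"])
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


_WRITERS = {
    BetaMatrix: ("beta.tsv", write_beta_matrix),
    DetectionMatrix: ("detection.tsv", write_detection_matrix),
    ProbeAnnotation: ("annotation.tsv", write_annotation),
    SampleSheet: ("samples.csv", write_sample_sheet),
}


def write_tables(objects: dict, out_dir) -> pd.DataFrame:
    """Write named objects to ``out_dir``; returns a manifest DataFrame.

    ``objects`` maps a base name to a domain object or a plain DataFrame
    (written as TSV with 6-decimal floats). Column order and float format
    are deterministic, so identical objects produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.tsv"
            obj.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep="NA")
            n = len(obj)
        elif isinstance(obj, list) and all(isinstance(o, ControlIntensities) for o in obj):
            path = out_dir / f"{name}.tsv"
            write_control_intensities(obj, path)
            n = len(obj)
        else:
            for cls, (suffix, writer) in _WRITERS.items():
                if isinstance(obj, cls):
                    path = out_dir / f"{name}{Path(suffix).suffix}"
                    writer(obj, path)
                    n = obj.values.shape[0] if hasattr(obj, "values") else len(obj.frame)
                    break
            else:
                raise TypeError(f"no writer for object of type {type(obj).__name__}")
        manifest.append({"file": path.name, "rows": n})
    manifest_frame = pd.DataFrame(manifest, columns=["file", "rows"])
    manifest_frame.to_csv(out_dir / "MANIFEST.tsv", sep="\t", index=False)
    return manifest_frame


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
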