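"""Core domain objects for 450K-style methylation analysis.

All containers are thin, validated wrappers around pandas/numpy structures:

* :class:`ProbeAnnotation` — probe identity, sequence context (CpG, CpH =
  non-CG, rs = genotyping, control), genomic coordinates and the 6-bp flank
  around the target cytosine.
* :class:`BetaMatrix` — probe x sample matrix of beta values, the methylated
  fraction of cells assayed, in [0, 1]; NaN marks missing.
* :class:`DetectionMatrix` — per probe x extract detection p-values (large
  values = measurement failed to rise above background).
* :class:`SampleSheet` — per-extract metadata: cell line, phenotype group
  (LDC = low / HDC = high endodermal differentiation capacity, or donor),
  batch covariates.
* :class:`ControlIntensities` — Infinium-I bisulfite-conversion control and
  negative-control intensities used for the conversion-efficiency statistic.
* :class:`CorridorTable` — per-promoter [lower, upper] reference methylation
  interval ("reference corridor").
* :class:`VariantTable` — known polymorphisms, for probe-level flags.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ProbeAnnotation",
    "BetaMatrix",
    "DetectionMatrix",
    "SampleSheet",
    "ControlIntensities",
    "CorridorTable",
    "VariantTable",
    "CONTEXTS",
    "GROUPS",
]

CONTEXTS = ("CpH", "CpG", "rs", "control")
GROUPS = ("LDC", "HDC", "donor", "unknown")
CELL_CLASSES = ("hiPSC", "hESC", "donor")

ANNOTATION_COLUMNS = ["probe_id", "context", "chromosome", "position", "strand", "flank6"]
SHEET_COLUMNS = [
    "sample_id",
    "line_id",
    "group",
    "cell_class",
    "passage",
    "batch",
    "slide",
    "array_position",
    "sex",
]


class FormatError(ValueError):
    """A file or table does not have the expected columns/shape."""


class ValidationError(ValueError):
    """A table has the right shape but violates a domain invariant."""


def _require_columns(frame: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(f"{what}: missing columns {missing}")


@dataclass
class ProbeAnnotation:
    """Probe annotation table, one row per probe, in canonical probe order."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.frame, ANNOTATION_COLUMNS, "probe annotation")
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        f = self.frame
        if f["probe_id"].duplicated().any():
            dup = f.loc[f["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe_id {dup!r}")
        bad_ctx = set(f["context"]) - set(CONTEXTS)
        if bad_ctx:
            raise ValidationError(f"unknown probe context(s) {sorted(bad_ctx)}")
        if (f["position"].astype(int) < 1).any():
            raise ValidationError("probe position must be >= 1 (1-based)")
        flank_len = f["flank6"].fillna("").astype(str).str.len()
        if (~flank_len.isin([0, 6])).any():
            bad = f.loc[~flank_len.isin([0, 6]), "probe_id"].iloc[0]
            raise ValidationError(f"flank6 must be empty or 6 bases (probe {bad!r})")
        if (~f["strand"].isin(["+", "-"])).any():
            raise ValidationError("strand must be '+' or '-'")

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.frame["probe_id"])

    def of_context(self, context: str) -> list[str]:
        """Probe ids of one sequence context, in canonical order."""
        return list(self.frame.loc[self.frame["context"] == context, "probe_id"])

    def subset(self, probe_ids) -> "ProbeAnnotation":
        keep = self.frame[self.frame["probe_id"].isin(set(probe_ids))]
        return ProbeAnnotation(keep.copy())


def _check_unit_interval(values: pd.DataFrame, what: str) -> None:
    arr = values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > 1) | np.isinf(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what}: value {arr[i, j]!r} out of [0,1] at probe "
            f"{values.index[i]!r}, sample {values.columns[j]!r}"
        )


@dataclass
class BetaMatrix:
    """Probe x sample beta values in [0, 1]; index=probe_id, columns=sample_id."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.validate()

    def validate(self) -> None:
        _check_unit_interval(self.values, "beta matrix")
        if self.values.index.duplicated().any():
            raise ValidationError("beta matrix: duplicate probe ids")
        if self.values.columns.duplicated().any():
            raise ValidationError("beta matrix: duplicate sample ids")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        wanted = set(probe_ids)
        keep = [p for p in self.values.index if p in wanted]
        return BetaMatrix(self.values.loc[keep])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        wanted = set(sample_ids)
        keep = [s for s in self.values.columns if s in wanted]
        return BetaMatrix(self.values[keep])


@dataclass
class DetectionMatrix:
    """Probe x extract detection p-values in [0, 1]; same layout as BetaMatrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unit_interval(self.values, "detection matrix")


@dataclass
class SampleSheet:
    """Per-extract metadata; one row per sample (DNA extract)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.frame, SHEET_COLUMNS, "sample sheet")
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        f = self.frame
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        bad = set(f["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group label(s) {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.frame["sample_id"])

    def line_of(self) -> pd.Series:
        """sample_id -> line_id mapping."""
        return self.frame.set_index("sample_id")["line_id"]

    def group_of_line(self) -> pd.Series:
        """line_id -> group label (first occurrence wins; groups are per line)."""
        return self.frame.drop_duplicates("line_id").set_index("line_id")["group"]

    def lines_in_group(self, group: str) -> list[str]:
        g = self.group_of_line()
        return list(g.index[g == group])

    def subset(self, sample_ids) -> "SampleSheet":
        keep = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        return SampleSheet(keep.copy())


@dataclass
class ControlIntensities:
    """Infinium-I conversion-control intensities for one sample (green channel).

    ``bic``: 3 converted-control intensities; ``biu``: 3 unconverted-control
    intensities; ``negatives``: negative-control intensities whose mean is the
    background estimate. Arbitrary fluorescence units, all >= 0.
    """

    sample_id: str
    bic: np.ndarray
    biu: np.ndarray
    negatives: np.ndarray

    def __post_init__(self) -> None:
        self.bic = np.asarray(self.bic, dtype=float)
        self.biu = np.asarray(self.biu, dtype=float)
        self.negatives = np.asarray(self.negatives, dtype=float)
        if self.bic.shape != (3,) or self.biu.shape != (3,):
            raise ValidationError(
                f"sample {self.sample_id!r}: expected 3 converted and 3 "
                f"unconverted control intensities"
            )
        if self.negatives.size < 1:
            raise ValidationError(f"sample {self.sample_id!r}: no negative controls")
        for name, arr in (("bic", self.bic), ("biu", self.biu), ("negatives", self.negatives)):
            if (arr < 0).any() or not np.isfinite(arr).all():
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name} intensities must be finite and >= 0"
                )


@dataclass
class CorridorTable:
    """Per-promoter reference methylation interval [lower, upper]."""

    frame: pd.DataFrame

    COLUMNS = ["promoter_id", "chromosome", "start", "end", "lower", "upper"]

    def __post_init__(self) -> None:
        _require_columns(self.frame, self.COLUMNS, "corridor table")
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        f = self.frame
        if (f["start"].astype(int) > f["end"].astype(int)).any():
            raise ValidationError("corridor: start > end")
        lo, up = f["lower"].astype(float), f["upper"].astype(float)
        if ((lo < 0) | (up > 1) | (lo > up)).any():
            raise ValidationError("corridor: need 0 <= lower <= upper <= 1")
        if f["promoter_id"].duplicated().any():
            raise ValidationError("corridor: duplicate promoter_id")


@dataclass
class VariantTable:
    """Known sequence variants: chromosome, 1-based position, ref, alt."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chromosome", "position", "ref", "alt"]))

    COLUMNS = ["chromosome", "position", "ref", "alt"]

    def __post_init__(self) -> None:
        _require_columns(self.frame, self.COLUMNS, "variant table")
        self.frame = self.frame.reset_index(drop=True)
        if len(self.frame) and (self.frame["position"].astype(int) < 1).any():
            raise ValidationError("variant position must be >= 1 (1-based)")
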