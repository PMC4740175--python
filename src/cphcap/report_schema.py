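"""Pydantic schema for the pipeline report bundle.

``schemas/report.schema.json`` in the installed package is generated from
:class:`ReportSchema` (see ``scripts`` in the repository); bundle validation
goes through :meth:`ReportSchema.model_validate`.
"""

from __future__ import annotations

from typing import Any

from pydantic import BaseModel, ConfigDict


class ResampleSummary(BaseModel):
    model_config = ConfigDict(extra="forbid")
    observed: float
    n_draws: int
    p_empirical: float | None
    max_abs_null: float
    quantiles: dict[str, float]
    exhaustive: bool
    seed: int | None


class ClassifierSummary(BaseModel):
    model_config = ConfigDict(extra="forbid")
    panel: list[str]
    threshold: float
    ldc_ci: list[float]
    hdc_ci: list[float]
    ci_overlap: bool


class ReportSchema(BaseModel):
    """Top-level report bundle; stage sections are optional."""

    model_config = ConfigDict(extra="forbid")

    config: dict[str, Any]
    seed: int
    version: str
    qc: dict[str, Any] | None = None
    mvp: dict[str, Any] | None = None
    delta: dict[str, Any] | None = None
    memory: dict[str, Any] | None = None
    motif: list[dict[str, Any]] | None = None
    resampling: dict[str, ResampleSummary | None] | None = None
    classifier: ClassifierSummary | None = None
    predictions: list[dict[str, Any]] | None = None
    evaluation: dict[str, Any] | None = None
    clustering: dict[str, Any] | None = None
    corridor: dict[str, Any] | None = None


def write_schema(path) -> None:
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps(ReportSchema.model_json_schema(), indent=1))
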