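"""Seeded generator of 450K-like methylation cohorts.

Emulates the structure of a two-group pluripotent stem-cell discovery study:
~2,676 autosomal CpH (non-CG) probes whose methylation separates lines of
high vs low endodermal differentiation capacity (HDC / LDC), a large CpG
probe pool with no group effect, a handful of rs genotyping probes that track
line identity, matched donor lines with low CpH methylation, per-line
replicate DNA extracts, detection p-values, and Infinium-I bisulfite
conversion control intensities.

Model (logit scale, natural log):

* CpH probe ``p`` in group ``g``:  beta = expit(theta_p + delta_g + l + e)
  with probe baseline theta_p ~ N(0, probe_sd_logit), a per-line scalar
  l ~ N(0, line_sd_logit) shared across all CpH probes of the line (global
  CpH level is a property of the line), and per-probe, per-extract noise
  e ~ N(0, extract_sd_logit).  delta_g is solved by bisection so the
  expected grand mean of beta equals the configured group mean (mu_hdc,
  mu_ldc, mu_donor) to within 1e-4.
* CpG probes: a ``cpg_meth_frac`` fraction centred near beta ~ 0.85, the rest
  near beta ~ 0.10; per-probe-per-line noise (no shared line scalar) plus
  extract noise; no group effect.
* rs probes: per line a genotype in {0, 1/2, 1} (Hardy-Weinberg at a random
  allele frequency), shared by all its extracts, read out near
  {0.03, 0.50, 0.97} with small noise.

Everything is driven by one integer seed; the same seed reproduces the
cohort bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import (
    BetaMatrix,
    ControlIntensities,
    DetectionMatrix,
    ProbeAnnotation,
    SampleSheet,
)

__all__ = [
    "GeneratorConfig",
    "ArtifactSpec",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_replication_cohort",
    "generate_control_intensities",
    "inject_artifacts",
    "generate_corridor",
]

_BASES = np.array(list("ACGT"))
_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]

# rs-probe beta read-out centres for genotypes 0 / 0.5 / 1
_RS_CENTRES = np.array([0.03, 0.50, 0.97])
_BETA_EPS = 1e-3


class ConfigError(ValueError):
    """Degenerate or inconsistent generator configuration."""


@dataclass
class GeneratorConfig:
    """Cohort design and calibration constants.

    Group means are means of beta (methylated fraction), not of logits:
    HDC ~ 50%, LDC ~ 37% CpH methylation, donors ~ 8%.  The 15/10 split of
    the 25 discovery lines between HDC and LDC is an assumption (only the
    total is pinned down by the study design); it is configurable.
    """

    n_hdc_lines: int = 15
    n_ldc_lines: int = 10
    n_donor_lines: int = 6
    extracts_per_line: int = 6
    n_cph: int = 2676
    n_cpg: int = 20000
    n_rs: int = 59
    mu_hdc: float = 0.50
    mu_ldc: float = 0.37
    mu_donor: float = 0.08
    probe_sd_logit: float = 0.8
    line_sd_logit: float = 0.15
    extract_sd_logit: float = 0.10
    cpg_meth_frac: float = 0.70
    conversion_rate: float = 0.995
    n_negative_controls: int = 613
    seed: int = 0

    def validate(self) -> None:
        for name in ("mu_hdc", "mu_ldc", "mu_donor", "cpg_meth_frac", "conversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must be in [0, 1]")
        for name in ("n_hdc_lines", "n_ldc_lines", "n_donor_lines",
                     "extracts_per_line", "n_cph", "n_cpg", "n_rs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")


@dataclass
class ArtifactSpec:
    """Counts of QC artifacts to plant in a cohort."""

    n_failed_probes: int = 0
    n_outlier_extracts: int = 0
    n_underconverted_samples: int = 0
    underconversion_rate: float = 0.90


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for oracle-style testing."""

    line_groups: dict[str, str]
    donor_map: dict[str, str]
    group_deltas: dict[str, float]
    probe_group_means: pd.DataFrame  # CpH probes x groups, expected beta
    cph_theta: pd.Series            # CpH probe logit baselines
    cpg_logit_means: pd.Series
    rs_genotypes: pd.DataFrame      # rs probes x lines, in {0, 0.5, 1}
    failed_probes: list[str] = field(default_factory=list)
    outlier_extracts: list[str] = field(default_factory=list)
    underconverted_samples: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "line_groups": self.line_groups,
            "donor_map": self.donor_map,
            "group_deltas": self.group_deltas,
            "failed_probes": self.failed_probes,
            "outlier_extracts": self.outlier_extracts,
            "underconverted_samples": self.underconverted_samples,
            "probe_group_means": self.probe_group_means.round(6).to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticCohort:
    beta: BetaMatrix
    detection: DetectionMatrix
    annotation: ProbeAnnotation
    sheet: SampleSheet
    controls: list[ControlIntensities]
    truth: SyntheticTruth


def _solve_group_shift(theta: np.ndarray, mu: float, noise_sd: float) -> float:
    """Bisection for the shift delta with mean_p E[expit(theta_p+delta+Z)] = mu.

    Z ~ N(0, noise_sd); the expectation uses 41-node Gauss-Hermite quadrature.
    Matches the target grand mean of beta to well under 1e-4.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(41)
    weights = weights / np.sqrt(np.pi)
    shift = np.sqrt(2.0) * noise_sd * nodes  # (41,)

    def grand_mean(delta: float) -> float:
        vals = expit(theta[:, None] + delta + shift[None, :])
        return float(np.mean(vals @ weights))

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if grand_mean(mid) < mu:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


def _random_flanks(rng: np.random.Generator, n: int, centre: str) -> list[str]:
    """6-mers with the target dinucleotide at positions 3-4 (1-based)."""
    left = rng.choice(_BASES, size=(n, 2))
    right = rng.choice(_BASES, size=(n, 2))
    if centre == "CpH":
        second = rng.choice(np.array(list("ATC")), size=n)
        mid = np.char.add("C", second.astype(str))
    else:
        mid = np.repeat("CG", n)
    return ["".join(l) + m + "".join(r) for l, m, r in
            zip(left.astype(str), np.asarray(mid, dtype=str), right.astype(str))]


def _make_annotation(rng: np.random.Generator, n_cph: int, n_cpg: int,
                     n_rs: int) -> ProbeAnnotation:
    n = n_cph + n_cpg + n_rs
    probe_ids = (
        [f"ch.{i:05d}" for i in range(1, n_cph + 1)]
        + [f"cg{i:08d}" for i in range(1, n_cpg + 1)]
        + [f"rs{i:07d}" for i in range(1, n_rs + 1)]
    )
    contexts = ["CpH"] * n_cph + ["CpG"] * n_cpg + ["rs"] * n_rs
    chroms = rng.choice(np.array(_AUTOSOMES), size=n)
    positions = rng.integers(10_000, 200_000_000, size=n)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    flanks = (_random_flanks(rng, n_cph, "CpH") + _random_flanks(rng, n_cpg, "CpG")
              + [""] * n_rs)
    frame = pd.DataFrame({
        "probe_id": probe_ids,
        "context": contexts,
        "chromosome": chroms,
        "position": positions,
        "strand": strands,
        "flank6": flanks,
    })
    return ProbeAnnotation(frame)


def _make_sheet(lines: list[tuple[str, str, str]], extracts_per_line: int,
                rng: np.random.Generator) -> SampleSheet:
    """lines: (line_id, group, cell_class) triples.

    Extracts are assigned to batches/slides/positions in randomized order
    (as a lab would randomize array layout), so technical covariates are
    not confounded with phenotype group.
    """
    rows = []
    for line_id, group, cell_class in lines:
        sex = rng.choice(["M", "F"])
        passage = int(rng.integers(8, 41)) if cell_class != "donor" else int(rng.integers(3, 11))
        for k in range(extracts_per_line):
            rows.append({
                "sample_id": f"{line_id}_e{k + 1}",
                "line_id": line_id,
                "group": group,
                "cell_class": cell_class,
                "passage": passage,
                "sex": sex,
            })
    layout = rng.permutation(len(rows))
    for row, slot in zip(rows, layout):
        slot = int(slot)
        row["batch"] = f"B{slot // 24 + 1}"
        row["slide"] = f"S{slot // 12 + 1}"
        row["array_position"] = f"R{slot % 6 + 1:02d}C{(slot // 6) % 2 + 1:02d}"
    return SampleSheet(pd.DataFrame(rows))


def generate_control_intensities(sample_ids, conversion_rate: float, seed,
                                 n_negatives: int = 613) -> list[ControlIntensities]:
    """Conversion-control intensities consistent with a true conversion rate.

    Negatives ~ N(150, 15); converted controls ~ N(150 + 5000*rate, 100);
    unconverted ~ N(150 + 5000*(1-rate), 100); everything floored at 0, so
    after background subtraction the efficiency statistic recovers
    ``100 * rate`` up to noise.
    """
    if not 0.0 <= conversion_rate <= 1.0:
        raise ConfigError(f"conversion_rate={conversion_rate} must be in [0, 1]")
    if isinstance(sample_ids, (int, np.integer)):
        sample_ids = [f"sample_{i + 1}" for i in range(int(sample_ids))]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for sid in sample_ids:
        neg = np.maximum(rng.normal(150.0, 15.0, size=n_negatives), 0.0)
        bic = np.maximum(rng.normal(150.0 + 5000.0 * conversion_rate, 100.0, size=3), 0.0)
        biu = np.maximum(rng.normal(150.0 + 5000.0 * (1.0 - conversion_rate), 100.0, size=3), 0.0)
        out.append(ControlIntensities(str(sid), bic, biu, neg))
    return out


@dataclass
class _ProbeModel:
    """Per-probe parameters shared by discovery and replication cohorts."""

    annotation: ProbeAnnotation
    cph_theta: pd.Series
    cpg_logit_means: pd.Series
    rs_allele_freqs: pd.Series
    group_deltas: dict[str, float]


def _draw_probe_model(cfg: GeneratorConfig, rng: np.random.Generator) -> _ProbeModel:
    annotation = _make_annotation(rng, cfg.n_cph, cfg.n_cpg, cfg.n_rs)
    cph_ids = annotation.of_context("CpH")
    cpg_ids = annotation.of_context("CpG")
    rs_ids = annotation.of_context("rs")

    theta = rng.normal(0.0, cfg.probe_sd_logit, size=cfg.n_cph)
    noise_sd = float(np.hypot(cfg.line_sd_logit, cfg.extract_sd_logit))
    deltas = {
        "HDC": _solve_group_shift(theta, cfg.mu_hdc, noise_sd),
        "LDC": _solve_group_shift(theta, cfg.mu_ldc, noise_sd),
        "donor": _solve_group_shift(theta, cfg.mu_donor, noise_sd),
    }

    meth = rng.random(cfg.n_cpg) < cfg.cpg_meth_frac
    cpg_means = np.where(meth,
                         rng.normal(logit(0.85), 0.4, size=cfg.n_cpg),
                         rng.normal(logit(0.10), 0.4, size=cfg.n_cpg))
    freqs = rng.uniform(0.2, 0.8, size=cfg.n_rs)
    return _ProbeModel(
        annotation=annotation,
        cph_theta=pd.Series(theta, index=cph_ids),
        cpg_logit_means=pd.Series(cpg_means, index=cpg_ids),
        rs_allele_freqs=pd.Series(freqs, index=rs_ids),
        group_deltas=deltas,
    )


def _draw_samples(cfg: GeneratorConfig, model: _ProbeModel,
                  lines: list[tuple[str, str, str]], extracts_per_line: int,
                  rng: np.random.Generator,
                  rs_genotypes: pd.DataFrame | None = None):
    """Draw beta/detection matrices and rs genotypes for the given lines."""
    ann = model.annotation
    cph_ids = ann.of_context("CpH")
    cpg_ids = ann.of_context("CpG")
    rs_ids = ann.of_context("rs")
    sheet = _make_sheet(lines, extracts_per_line, rng)
    sample_ids = list(sheet.sample_ids)
    n_samples = len(sample_ids)

    theta = model.cph_theta.to_numpy()
    cpg_mu = model.cpg_logit_means.to_numpy()

    if rs_genotypes is None:
        geno = {}
        for line_id, _, _ in lines:
            q = model.rs_allele_freqs.to_numpy()
            geno[line_id] = rng.binomial(2, q) / 2.0
        rs_genotypes = pd.DataFrame(geno, index=rs_ids)
    else:
        # replication lines get fresh genotypes for any line not already known
        geno = {c: rs_genotypes[c].to_numpy() for c in rs_genotypes.columns}
        for line_id, _, _ in lines:
            if line_id not in geno:
                geno[line_id] = rng.binomial(2, model.rs_allele_freqs.to_numpy()) / 2.0
        rs_genotypes = pd.DataFrame(geno, index=rs_ids)

    rs_read_sd = 0.01 if cfg.extract_sd_logit > 0 else 0.0
    line_scalars = {line_id: rng.normal(0.0, cfg.line_sd_logit) for line_id, _, _ in lines}
    # per-probe-per-line CpG variation (no shared line scalar for CpG)
    cpg_line = {line_id: rng.normal(0.0, cfg.line_sd_logit, size=len(cpg_ids))
                for line_id, _, _ in lines}

    blocks = np.empty((len(cph_ids) + len(cpg_ids) + len(rs_ids), n_samples))
    line_of = sheet.line_of()
    group_of = sheet.frame.set_index("sample_id")["group"]
    for j, sid in enumerate(sample_ids):
        line_id = line_of[sid]
        g = group_of[sid]
        delta = model.group_deltas[g]
        e_cph = rng.normal(0.0, cfg.extract_sd_logit, size=len(cph_ids))
        cph = expit(theta + delta + line_scalars[line_id] + e_cph)
        e_cpg = rng.normal(0.0, cfg.extract_sd_logit, size=len(cpg_ids))
        cpg = expit(cpg_mu + cpg_line[line_id] + e_cpg)
        g_idx = np.rint(rs_genotypes[line_id].to_numpy() * 2).astype(int)
        rs = np.clip(_RS_CENTRES[g_idx] + rng.normal(0.0, rs_read_sd, size=len(rs_ids)),
                     _BETA_EPS, 1 - _BETA_EPS)
        blocks[:, j] = np.concatenate([cph, cpg, rs])

    beta = BetaMatrix(pd.DataFrame(blocks, index=cph_ids + cpg_ids + rs_ids,
                                   columns=sample_ids))
    detp = DetectionMatrix(pd.DataFrame(
        rng.uniform(0.0, 0.005, size=blocks.shape),
        index=beta.probe_ids, columns=sample_ids))
    return beta, detp, sheet, rs_genotypes


def _truth_from(model: _ProbeModel, lines, donor_map, rs_genotypes) -> SyntheticTruth:
    means = {g: expit(model.cph_theta.to_numpy() + d)
             for g, d in model.group_deltas.items()}
    probe_means = pd.DataFrame(means, index=model.cph_theta.index)
    return SyntheticTruth(
        line_groups={line_id: group for line_id, group, _ in lines},
        donor_map=donor_map,
        group_deltas=dict(model.group_deltas),
        probe_group_means=probe_means,
        cph_theta=model.cph_theta,
        cpg_logit_means=model.cpg_logit_means,
        rs_genotypes=rs_genotypes,
    )


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the discovery cohort: HDC/LDC hiPSC lines plus donor lines."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    lines = (
        [(f"HDC{i + 1:02d}", "HDC", "hiPSC") for i in range(config.n_hdc_lines)]
        + [(f"LDC{i + 1:02d}", "LDC", "hiPSC") for i in range(config.n_ldc_lines)]
        + [(f"DON{i + 1:02d}", "donor", "donor") for i in range(config.n_donor_lines)]
    )
    # donors partition into HDC-derived and LDC-derived sets (proportional),
    # so donor-vs-donor contrasts are well defined
    n_total = config.n_hdc_lines + config.n_ldc_lines
    if config.n_donor_lines >= 2:
        n_hdc_donors = min(config.n_donor_lines - 1,
                           max(1, round(config.n_donor_lines * config.n_hdc_lines / n_total)))
    else:
        n_hdc_donors = 1  # single donor serves both phenotype groups
    n_ldc_donors = max(1, config.n_donor_lines - n_hdc_donors)
    ldc_offset = config.n_donor_lines - n_ldc_donors
    donor_map = {}
    for i in range(config.n_hdc_lines):
        donor_map[f"HDC{i + 1:02d}"] = f"DON{i % n_hdc_donors + 1:02d}"
    for i in range(config.n_ldc_lines):
        donor_map[f"LDC{i + 1:02d}"] = f"DON{ldc_offset + i % n_ldc_donors + 1:02d}"

    model = _draw_probe_model(config, rng)
    beta, detp, sheet, rs_geno = _draw_samples(
        config, model, lines, config.extracts_per_line, rng)
    controls = generate_control_intensities(
        list(sheet.sample_ids), config.conversion_rate, rng,
        n_negatives=config.n_negative_controls)
    truth = _truth_from(model, lines, donor_map, rs_geno)
    # keep the probe model around so replication cohorts can share it
    truth._probe_model = model  # type: ignore[attr-defined]
    return SyntheticCohort(beta, detp, model.annotation, sheet, controls, truth)


def generate_replication_cohort(truth: SyntheticTruth, seed,
                                n_hdc: int = 5, n_ldc: int = 5,
                                n_hesc: int = 3,
                                extracts_per_line: int = 1,
                                config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Independent lines measured on the same probes as a discovery cohort.

    Probe-level parameters (baselines, group shifts) are locus properties and
    are reused from the discovery truth; lines, extracts, genotypes and
    measurement noise are drawn fresh.  Default: 10 new lines with single
    extracts, the first ``n_hesc`` HDC lines labelled hESC.
    """
    model: _ProbeModel = getattr(truth, "_probe_model", None)
    if model is None:
        raise ValueError("truth object does not carry probe-level parameters")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    lines = (
        [(f"REP-H{i + 1:02d}", "HDC", "hESC" if i < n_hesc else "hiPSC")
         for i in range(n_hdc)]
        + [(f"REP-L{i + 1:02d}", "LDC", "hiPSC") for i in range(n_ldc)]
    )
    beta, detp, sheet, rs_geno = _draw_samples(cfg, model, lines,
                                               extracts_per_line, rng)
    controls = generate_control_intensities(list(sheet.sample_ids),
                                            cfg.conversion_rate, rng,
                                            n_negatives=cfg.n_negative_controls)
    rep_truth = _truth_from(model, lines, {}, rs_geno)
    rep_truth._probe_model = model  # type: ignore[attr-defined]
    return SyntheticCohort(beta, detp, model.annotation, sheet, controls, rep_truth)


def inject_artifacts(cohort: SyntheticCohort, spec: ArtifactSpec,
                     seed) -> SyntheticCohort:
    """Plant QC artifacts into a cohort and record them in the truth registry.

    * failed probes: detection p resampled from U(0.05, 1) in one extract;
    * outlier extracts: rs-probe betas replaced by another line's genotypes
      (a sample swap);
    * under-converted samples: beta -> 1 - c*(1 - beta) on every probe
      (unconverted cytosines read as methylated) and control intensities
      regenerated at conversion rate c.
    """
    rng = np.random.default_rng(seed)
    beta = cohort.beta.values.copy()
    detp = cohort.detection.values.copy()
    truth = cohort.truth
    sample_ids = list(beta.columns)
    ann = cohort.annotation
    rs_ids = ann.of_context("rs")

    n_avail_probes = beta.shape[0]
    if spec.n_failed_probes > n_avail_probes:
        raise ValueError(
            f"requested {spec.n_failed_probes} failed probes, only "
            f"{n_avail_probes} available")
    if spec.n_outlier_extracts + spec.n_underconverted_samples > len(sample_ids):
        raise ValueError("requested more artifact samples than samples exist")

    failed = list(rng.choice(beta.index.to_numpy(), size=spec.n_failed_probes,
                             replace=False))
    for probe in failed:
        extract = rng.choice(sample_ids)
        detp.loc[probe, extract] = rng.uniform(0.05, 1.0)

    chosen = list(rng.choice(np.array(sample_ids),
                             size=spec.n_outlier_extracts + spec.n_underconverted_samples,
                             replace=False))
    outliers = chosen[:spec.n_outlier_extracts]
    underconv = chosen[spec.n_outlier_extracts:]

    line_of = cohort.sheet.line_of()
    lines = list(dict.fromkeys(line_of))
    for sid in outliers:
        own = line_of[sid]
        other = rng.choice([l for l in lines if l != own])
        g_idx = np.rint(truth.rs_genotypes[other].to_numpy() * 2).astype(int)
        beta.loc[rs_ids, sid] = np.clip(
            _RS_CENTRES[g_idx] + rng.normal(0.0, 0.01, size=len(rs_ids)),
            _BETA_EPS, 1 - _BETA_EPS)

    controls = {ci.sample_id: ci for ci in cohort.controls}
    for sid in underconv:
        c = spec.underconversion_rate
        beta[sid] = 1.0 - c * (1.0 - beta[sid])
        controls[sid] = generate_control_intensities([sid], c, rng)[0]

    new_truth = SyntheticTruth(
        line_groups=dict(truth.line_groups),
        donor_map=dict(truth.donor_map),
        group_deltas=dict(truth.group_deltas),
        probe_group_means=truth.probe_group_means,
        cph_theta=truth.cph_theta,
        cpg_logit_means=truth.cpg_logit_means,
        rs_genotypes=truth.rs_genotypes,
        failed_probes=truth.failed_probes + [str(p) for p in failed],
        outlier_extracts=truth.outlier_extracts + [str(s) for s in outliers],
        underconverted_samples={**truth.underconverted_samples,
                                **{str(s): spec.underconversion_rate for s in underconv}},
    )
    if hasattr(truth, "_probe_model"):
        new_truth._probe_model = truth._probe_model  # type: ignore[attr-defined]
    return SyntheticCohort(BetaMatrix(beta), DetectionMatrix(detp),
                           cohort.annotation, cohort.sheet,
                           list(controls.values()), new_truth)


def generate_corridor(cohort: SyntheticCohort, seed, probes_per_promoter: int = 4,
                      halfwidth: float = 0.15, miss_fraction: float = 0.2):
    """Build a reference-corridor table over the cohort's CpG probes.

    Consecutive CpG probes (position order, per chromosome) are grouped into
    promoters of ``probes_per_promoter`` probes; each promoter's corridor is
    centred on the cohort median of its member probes with the given
    halfwidth, except a ``miss_fraction`` of promoters whose corridor is
    shifted off-centre to plant near-misses.  Returns a
    :class:`~cphcap.datatypes.CorridorTable`.
    """
    from .datatypes import CorridorTable

    rng = np.random.default_rng(seed)
    ann = cohort.annotation.frame
    cpg = ann[ann["context"] == "CpG"].sort_values(["chromosome", "position"])
    probe_median = cohort.beta.values.median(axis=1, skipna=True)
    rows = []
    pid = 0
    for chrom, grp in cpg.groupby("chromosome", sort=True):
        ids = grp["probe_id"].to_numpy()
        pos = grp["position"].to_numpy()
        med_by_probe = probe_median.loc[ids].to_numpy()
        for i in range(0, len(ids) - probes_per_promoter + 1, probes_per_promoter):
            med = float(np.median(med_by_probe[i:i + probes_per_promoter]))
            centre = med
            if rng.random() < miss_fraction:
                centre = med + rng.choice([-1, 1]) * (halfwidth + rng.uniform(0.01, 0.1))
            lower = float(np.clip(centre - halfwidth, 0.0, 1.0))
            upper = float(np.clip(centre + halfwidth, 0.0, 1.0))
            pid += 1
            rows.append({"promoter_id": f"prom{pid:05d}", "chromosome": chrom,
                         "start": int(pos[i]), "end": int(pos[i + probes_per_promoter - 1]),
                         "lower": min(lower, upper), "upper": max(lower, upper)})
    return CorridorTable(pd.DataFrame(rows))


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write all cohort tables in the package's interchange formats."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_tables({
        "beta": cohort.beta,
        "detection": cohort.detection,
        "annotation": cohort.annotation,
        "samples": cohort.sheet,
        "controls": cohort.controls,
    }, out)
    cohort.truth.to_json(out / "truth.json")
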