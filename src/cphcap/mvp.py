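"""Differential non-CG methylation: MVP calling and group contrasts.

Statistical core:

* :func:`beta_to_m` — beta values are logit transformed to M-values,
  ``M = log2(beta / (1 - beta))``, to stabilise variance before testing.
* :func:`fit_moderated_t` — per-probe two-group moderated t-test with
  empirical-Bayes variance shrinkage: the per-probe residual variance
  ``s_g^2`` (pooled, ``d_g = n1 + n2 - 2`` df) is shrunk toward a prior
  ``(d0, s0^2)`` estimated by moment-matching the scaled-F marginal of the
  sample variances on the log scale (digamma/trigamma equations); the
  posterior variance is ``(d0*s0^2 + d_g*s_g^2) / (d0 + d_g)`` and the
  moderated t has ``d0 + d_g`` degrees of freedom (capped at the pooled df).
* :func:`call_mvps` — Benjamini-Hochberg q-values; a probe is a methylation
  variable position (MVP) at q <= fdr, hyper- or hypo- by the sign of
  delta-beta (high-capacity minus low-capacity group mean).
* :func:`group_delta` — the headline contrast: per-line mean beta across
  probes, Welch two-sample t between groups, 95% CI of the difference.
* :func:`memory_delta` — donor "epigenetic memory" contrasts: per matched
  line-donor pair, delta beta-mean; plus a donor-vs-donor group contrast.
* :func:`motif_effect_summary` — effect size stratified by the 6-bp flank.

Replicate extracts are averaged to line level *before* testing; the line is
the unit of analysis throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import BetaMatrix

__all__ = [
    "MVPTable",
    "DeltaResult",
    "beta_to_m",
    "fit_moderated_t",
    "call_mvps",
    "group_delta",
    "memory_delta",
    "motif_effect_summary",
    "trigamma_inverse",
]


def _as_frame(x) -> pd.DataFrame:
    return x.values if isinstance(x, BetaMatrix) else x


def beta_to_m(beta, epsilon: float = 1e-6) -> pd.DataFrame:
    """M = log2(beta/(1-beta)) after clamping beta into [eps, 1-eps]."""
    b = _as_frame(beta).clip(lower=epsilon, upper=1.0 - epsilon)
    return np.log2(b / (1.0 - b))


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` on the open interval."""
    p = np.power(2.0, m)
    return p / (1.0 + p)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration on 1/trigamma."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled-F marginal to sample variances on the log scale.

    Returns ``(d0, s0^2)``; ``d0`` may be ``inf`` when the observed spread of
    log-variances is no wider than sampling noise alone.
    """
    ok = (df > 0) & (s2 > 0) & np.isfinite(s2)
    if ok.sum() < 2:
        raise ValueError("need >= 2 probes with positive residual variance "
                         "to estimate the variance prior")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


@dataclass
class MVPTable:
    """Per-probe differential methylation results plus shrinkage globals."""

    frame: pd.DataFrame  # index probe_id; columns below
    d0: float
    s02: float
    fdr: float | None = None

    COLUMNS = ["mean_high", "mean_low", "delta_beta", "s2", "df", "t", "p",
               "q", "direction", "significant"]

    @property
    def significant_probes(self) -> list[str]:
        if "significant" not in self.frame:
            return []
        return list(self.frame.index[self.frame["significant"]])

    def summary(self) -> dict:
        out = {
            "n_probes": int(len(self.frame)),
            "d0": None if np.isinf(self.d0) else float(self.d0),
            "s02": float(self.s02),
            "fdr": self.fdr,
        }
        if "significant" in self.frame:
            sig = self.frame["significant"]
            out["n_significant"] = int(sig.sum())
            out["n_hyper"] = int((sig & (self.frame["direction"] == "hyper")).sum())
            out["n_hypo"] = int((sig & (self.frame["direction"] == "hypo")).sum())
        return out


def fit_moderated_t(m: pd.DataFrame, groups: Mapping[str, str],
                    beta: pd.DataFrame | None = None,
                    group_high: str = "HDC", group_low: str = "LDC",
                    d0_override: float | None = None) -> MVPTable:
    """Empirical-Bayes moderated two-group t-test, one test per probe.

    ``m`` is a probe x line M-value matrix; ``groups`` maps line_id to a
    group label. Delta-beta (and the reported group means) come from
    ``beta`` when given, else from back-transformed M-values.
    ``d0_override`` forces the prior df (``np.inf`` gives the pure-prior
    limit, ``0`` the ordinary t-test).
    """
    high = [l for l in m.columns if groups.get(l) == group_high]
    low = [l for l in m.columns if groups.get(l) == group_low]
    n1, n2 = len(high), len(low)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 lines per group, got {n1} {group_high} "
                         f"and {n2} {group_low}")

    x1 = m[high].to_numpy(dtype=float)
    x2 = m[low].to_numpy(dtype=float)
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    dg = float(n1 + n2 - 2)
    s2 = ss / dg
    df = np.full(len(m), dg)

    if d0_override is not None:
        d0 = float(d0_override)
        _, s02 = _fit_variance_prior(s2, df)
    else:
        d0, s02 = _fit_variance_prior(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    elif d0 == 0.0:
        s2_post = s2
    else:
        s2_post = (d0 * s02 + dg * s2) / (d0 + dg)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    tstat = (mean1 - mean2) / se
    df_pooled = dg * len(m)
    df_total = min(d0 + dg, df_pooled) if np.isfinite(d0) else df_pooled
    p = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    bsrc = beta if beta is not None else m_to_beta(m)
    bmean1 = bsrc[high].mean(axis=1).reindex(m.index).to_numpy()
    bmean2 = bsrc[low].mean(axis=1).reindex(m.index).to_numpy()
    delta = bmean1 - bmean2

    frame = pd.DataFrame({
        "mean_high": bmean1,
        "mean_low": bmean2,
        "delta_beta": delta,
        "s2": s2,
        "df": df,
        "t": tstat,
        "p": p,
        "direction": np.where(delta > 0, "hyper", "hypo"),
    }, index=m.index)
    return MVPTable(frame, d0=d0, s02=s02)


def call_mvps(table: MVPTable, fdr: float = 0.05) -> MVPTable:
    """Attach Benjamini-Hochberg q-values and the significance call."""
    frame = table.frame.copy()
    _, q, _, _ = multipletests(frame["p"].to_numpy(), method="fdr_bh")
    frame["q"] = q
    frame["significant"] = frame["q"] <= fdr
    return MVPTable(frame, d0=table.d0, s02=table.s02, fdr=fdr)


@dataclass
class DeltaResult:
    """Between-group difference of mean beta with Welch inference."""

    delta: float
    ci: tuple[float, float]
    t: float
    p: float
    df: float
    group_stats: dict  # label -> {mean, ci, n, sd}
    line_means: pd.Series
    ci_defined: bool = True

    def summary(self) -> dict:
        return {
            "delta_beta_mean": float(self.delta),
            "ci95": [float(self.ci[0]), float(self.ci[1])],
            "t": float(self.t),
            "p": float(self.p),
            "df": float(self.df),
            "groups": {g: {k: (list(map(float, v)) if isinstance(v, tuple) else
                              (float(v) if v == v else None))
                           for k, v in s.items()} for g, s in self.group_stats.items()},
        }


def _group_ci(values: np.ndarray, level: float = 0.95):
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, (np.nan, np.nan), np.nan
    sd = float(np.std(values, ddof=1))
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / np.sqrt(n)
    return mean, (mean - half, mean + half), sd


def group_delta(line_beta, groups: Mapping[str, str],
                group_high: str = "HDC", group_low: str = "LDC",
                level: float = 0.95) -> DeltaResult:
    """Welch contrast of per-line mean beta between two groups.

    Each line is reduced to its mean beta across probes (pairwise-complete);
    the difference ``mean(high) - mean(low)`` is tested with an
    unequal-variance two-sample t and reported with a t-based CI, along with
    each group's own mean and CI (the classifier threshold feeds on these).
    """
    frame = _as_frame(line_beta)
    line_means = frame.mean(axis=0, skipna=True)
    v1 = line_means[[l for l in line_means.index if groups.get(l) == group_high]]
    v2 = line_means[[l for l in line_means.index if groups.get(l) == group_low]]
    n1, n2 = len(v1), len(v2)
    if n1 < 1 or n2 < 1:
        raise ValueError(f"empty group: {group_high} n={n1}, {group_low} n={n2}")

    mean1, ci1, sd1 = _group_ci(v1.to_numpy(), level)
    mean2, ci2, sd2 = _group_ci(v2.to_numpy(), level)
    delta = mean1 - mean2
    ci_defined = n1 >= 2 and n2 >= 2
    if ci_defined:
        var1, var2 = sd1 ** 2, sd2 ** 2
        se = np.sqrt(var1 / n1 + var2 / n2)
        if se == 0.0:
            tstat, p, dfw, ci = 0.0, 1.0, float(n1 + n2 - 2), (delta, delta)
        else:
            dfw = (var1 / n1 + var2 / n2) ** 2 / (
                (var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1))
            tstat = float(delta / se)
            p = float(2.0 * stats.t.sf(abs(tstat), dfw))
            half = stats.t.ppf(0.5 + level / 2.0, dfw) * se
            ci = (delta - half, delta + half)
    else:
        tstat, p, dfw, ci = np.nan, np.nan, np.nan, (np.nan, np.nan)

    return DeltaResult(
        delta=float(delta), ci=ci, t=tstat, p=p, df=dfw,
        group_stats={
            group_high: {"mean": mean1, "ci": ci1, "n": n1, "sd": sd1},
            group_low: {"mean": mean2, "ci": ci2, "n": n2, "sd": sd2},
        },
        line_means=line_means, ci_defined=ci_defined,
    )


def memory_delta(line_beta, donor_map: Mapping[str, str],
                 groups: Mapping[str, str]):
    """Donor epigenetic-memory contrasts on CpH methylation.

    For every hiPSC line with a matched donor line present in the matrix,
    reports ``delta = line beta-mean - donor beta-mean``; summarises per
    phenotype group, and contrasts HDC-derived donors against LDC-derived
    donors (expected not significant). Unmatched lines are skipped and
    listed. Returns ``(pairs frame, group summary dict, donor DeltaResult
    or None, skipped)``.
    """
    frame = _as_frame(line_beta)
    line_means = frame.mean(axis=0, skipna=True)
    rows, skipped = [], []
    donor_group: dict[str, str] = {}
    for line_id, group in groups.items():
        if group not in ("HDC", "LDC") or line_id not in line_means.index:
            continue
        donor = donor_map.get(line_id)
        if donor is None or donor not in line_means.index:
            skipped.append(line_id)
            continue
        rows.append({"line_id": line_id, "donor_id": donor, "group": group,
                     "line_mean": float(line_means[line_id]),
                     "donor_mean": float(line_means[donor]),
                     "delta": float(line_means[line_id] - line_means[donor])})
        donor_group.setdefault(donor, group)
    pairs = pd.DataFrame(rows, columns=["line_id", "donor_id", "group",
                                        "line_mean", "donor_mean", "delta"])
    summary = {g: float(pairs.loc[pairs["group"] == g, "delta"].mean())
               for g in ("HDC", "LDC") if (pairs["group"] == g).any()}

    donors = [d for d in donor_group if d in line_means.index]
    donor_result = None
    n_h = sum(donor_group[d] == "HDC" for d in donors)
    n_l = sum(donor_group[d] == "LDC" for d in donors)
    if n_h >= 2 and n_l >= 2:
        donor_result = group_delta(frame[donors], donor_group)
    return pairs, summary, donor_result, skipped


def motif_effect_summary(table: MVPTable, annotation, min_n: int = 5) -> pd.DataFrame:
    """Effect size per 6-bp flank motif around the non-CG target.

    Motifs with fewer than ``min_n`` probes are pooled as ``other``. Columns:
    n probes, mean delta-beta, fraction of probes called in the hyper
    direction.
    """
    ann = annotation.frame if hasattr(annotation, "frame") else annotation
    flank = ann.set_index("probe_id")["flank6"].reindex(table.frame.index)
    flank = flank.fillna("").astype(str)
    if (flank == "").all():
        raise ValueError("no probe has a 6-bp flank annotation")
    counts = flank.value_counts()
    label = flank.where(flank.map(counts) >= min_n, other="other")
    grp = table.frame.groupby(label.to_numpy())
    out = pd.DataFrame({
        "n": grp.size(),
        "mean_delta_beta": grp["delta_beta"].mean(),
        "fraction_hyper": grp.apply(
            lambda g: float((g["delta_beta"] > 0).mean()), include_groups=False),
    })
    out.index.name = "flank6"
    return out.sort_index()
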