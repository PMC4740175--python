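"""Empirical null distributions for the between-group methylation contrast.

* :func:`permutation_test_delta` — permute group labels over lines and
  recompute the difference in mean beta each draw; two-sided add-one
  empirical p, ``p = (1 + #{|null| >= |obs|}) / (B + 1)``. When the number
  of distinct label assignments does not exceed B, the test switches to
  exhaustive enumeration.
* :func:`montecarlo_cpg_null` — draw random subsets of CpG probes (the
  contexts where no group effect is expected) of the same size as the CpH
  panel and recompute the group contrast on each subset; reports the
  maximum absolute difference and quantiles.  ``beta_min`` restricts the
  pool to probes whose pooled mean beta exceeds the cutoff (e.g. 0.80 for
  "solely methylated" CpGs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix

__all__ = ["ResampleResult", "permutation_test_delta", "montecarlo_cpg_null"]


@dataclass
class ResampleResult:
    """Observed statistic against an empirical null."""

    observed: float
    n_draws: int
    p_empirical: float | None
    max_abs: float
    quantiles: dict[str, float]
    exhaustive: bool
    seed: int | None
    null_draws: np.ndarray | None = None

    def summary(self) -> dict:
        return {
            "observed": float(self.observed),
            "n_draws": int(self.n_draws),
            "p_empirical": None if self.p_empirical is None else float(self.p_empirical),
            "max_abs_null": float(self.max_abs),
            "quantiles": {k: float(v) for k, v in self.quantiles.items()},
            "exhaustive": bool(self.exhaustive),
            "seed": self.seed,
        }


def _as_frame(x) -> pd.DataFrame:
    return x.values if isinstance(x, BetaMatrix) else x


def _quantiles(draws: np.ndarray) -> dict[str, float]:
    qs = [0.5, 0.9, 0.95, 0.99, 1.0]
    vals = np.quantile(np.abs(draws), qs)
    return {f"q{int(q * 100)}": float(v) for q, v in zip(qs, vals)}


def permutation_test_delta(line_beta, groups: Mapping[str, str], B: int = 20000,
                           seed: int | None = None, group_high: str = "HDC",
                           group_low: str = "LDC",
                           keep_draws: bool = False) -> ResampleResult:
    """Label-permutation null for the between-group difference of beta-means.

    The statistic is ``mean over high-group lines - mean over low-group
    lines`` of per-line mean beta. Labels are permuted over lines without
    replacement; significance is two-sided on |delta| with the add-one
    estimator.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    frame = _as_frame(line_beta)
    lines = [l for l in frame.columns if groups.get(l) in (group_high, group_low)]
    line_means = frame[lines].mean(axis=0, skipna=True).to_numpy()
    is_high = np.array([groups[l] == group_high for l in lines])
    n, n1 = len(lines), int(is_high.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be non-empty")

    observed = float(line_means[is_high].mean() - line_means[~is_high].mean())
    n_assignments = comb(n, n1)
    exhaustive = n_assignments <= B
    if exhaustive:
        draws = np.empty(n_assignments)
        total = line_means.sum()
        for i, idx in enumerate(combinations(range(n), n1)):
            s1 = line_means[list(idx)].sum()
            draws[i] = s1 / n1 - (total - s1) / (n - n1)
    else:
        rng = np.random.default_rng(seed)
        draws = np.empty(B)
        total = line_means.sum()
        for i in range(B):
            idx = rng.choice(n, size=n1, replace=False)
            s1 = line_means[idx].sum()
            draws[i] = s1 / n1 - (total - s1) / (n - n1)

    n_extreme = int(np.sum(np.abs(draws) >= abs(observed) - 1e-15))
    if exhaustive:
        # the observed assignment is one of the enumerated ones
        p = n_extreme / n_assignments
    else:
        p = (1 + n_extreme) / (len(draws) + 1)
    return ResampleResult(
        observed=observed, n_draws=len(draws), p_empirical=float(p),
        max_abs=float(np.max(np.abs(draws))), quantiles=_quantiles(draws),
        exhaustive=exhaustive, seed=seed,
        null_draws=draws if keep_draws else None)


def montecarlo_cpg_null(cpg_line_beta, groups: Mapping[str, str],
                        n_probes: int = 2676, B: int = 10000,
                        seed: int | None = None, beta_min: float | None = None,
                        group_high: str = "HDC", group_low: str = "LDC",
                        keep_draws: bool = False) -> ResampleResult:
    """Monte Carlo probe-subsampling null on CpG probes.

    Each draw samples ``n_probes`` CpG probes without replacement and
    recomputes the between-group difference of per-line mean beta on that
    subset. ``beta_min`` (e.g. 0.80) first restricts the pool to probes whose
    pooled mean beta exceeds the cutoff. The headline summary is the maximum
    |difference| over draws.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    frame = _as_frame(cpg_line_beta)
    high = [l for l in frame.columns if groups.get(l) == group_high]
    low = [l for l in frame.columns if groups.get(l) == group_low]
    if not high or not low:
        raise ValueError("both groups must be non-empty")

    pool = frame
    if beta_min is not None:
        pooled_mean = frame[high + low].mean(axis=1, skipna=True)
        pool = frame.loc[pooled_mean > beta_min]
    if len(pool) < n_probes:
        raise ValueError(
            f"CpG pool has {len(pool)} probes after restriction; "
            f"cannot sample {n_probes}")

    # per-probe difference of group means; a subset's delta is its mean
    d = (pool[high].mean(axis=1, skipna=True)
         - pool[low].mean(axis=1, skipna=True)).to_numpy()
    observed = float(d.mean())

    rng = np.random.default_rng(seed)
    draws = np.empty(B)
    npool = len(d)
    for i in range(B):
        idx = rng.choice(npool, size=n_probes, replace=False)
        draws[i] = d[idx].mean()

    p = (1 + int(np.sum(np.abs(draws) >= abs(observed) - 1e-15))) / (B + 1)
    return ResampleResult(
        observed=observed, n_draws=B, p_empirical=float(p),
        max_abs=float(np.max(np.abs(draws))), quantiles=_quantiles(draws),
        exhaustive=False, seed=seed,
        null_draws=draws if keep_draws else None)
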