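"""Shared fixtures: one full-size seeded cohort reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cphcap as cc
from cphcap.mvp import beta_to_m, call_mvps, fit_moderated_t
from cphcap.qc import average_replicates, run_qc

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort() -> cc.SyntheticCohort:
    """Full-size discovery cohort at the generator defaults."""
    return cc.generate_cohort(cc.GeneratorConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def qc_products(default_cohort):
    beta_qc, sheet_qc, report = run_qc(
        default_cohort.beta, default_cohort.detection, default_cohort.annotation,
        default_cohort.sheet, controls=default_cohort.controls)
    return beta_qc, sheet_qc, report


@pytest.fixture(scope="session")
def line_matrix(qc_products) -> cc.BetaMatrix:
    beta_qc, sheet_qc, _ = qc_products
    return average_replicates(beta_qc, sheet_qc)


@pytest.fixture(scope="session")
def line_groups(qc_products) -> dict:
    _, sheet_qc, _ = qc_products
    return sheet_qc.group_of_line().to_dict()


@pytest.fixture(scope="session")
def cph_lines(default_cohort, line_matrix, line_groups) -> pd.DataFrame:
    """Line-level CpH beta over hiPSC (HDC/LDC) lines only."""
    cph = default_cohort.annotation.of_context("CpH")
    hip = [l for l, g in line_groups.items() if g in ("HDC", "LDC")]
    return line_matrix.values.loc[cph, hip]


@pytest.fixture(scope="session")
def mvp_table(cph_lines, line_groups) -> cc.MVPTable:
    m = beta_to_m(cph_lines)
    return call_mvps(fit_moderated_t(m, line_groups, beta=cph_lines), fdr=0.05)


@pytest.fixture
def small_cohort() -> cc.SyntheticCohort:
    """Cheap cohort for tests that mutate or regenerate data."""
    return cc.generate_cohort(cc.GeneratorConfig(
        seed=5, n_cph=200, n_cpg=300, n_rs=20, n_hdc_lines=4, n_ldc_lines=3,
        n_donor_lines=2, extracts_per_line=3))


def toy_m_matrix() -> pd.DataFrame:
    """20-probe x 10-line heteroscedastic M-value matrix (5 vs 5 design).

    Deterministic (values rounded to 6 decimals); the expected moderated-t
    results for this exact matrix were computed once with an independent
    implementation of the same shrinkage estimator and frozen in
    test_mvp.py.
    """
    rng = np.random.default_rng(42)
    sd = rng.uniform(0.2, 1.5, size=20)
    effect = rng.normal(0, 1.0, size=20)
    x = rng.normal(0, 1, size=(20, 10)) * sd[:, None]
    x[:, :5] += effect[:, None]
    x = np.round(x, 6)
    return pd.DataFrame(x, index=[f"p{i:02d}" for i in range(20)],
                        columns=[f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)])
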