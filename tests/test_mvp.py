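"""Differential-methylation statistics: transform, shrinkage t, contrasts.

The moderated-t expectations (prior df, prior variance, per-probe t/p) for
the toy matrix in conftest were computed once with an independent reference
implementation of the same published empirical-Bayes estimator and frozen
here; the test requires agreement to 1e-6.
"""

import numpy as np
import pandas as pd
import pytest

from cphcap.datatypes import ProbeAnnotation
from cphcap.mvp import (
    beta_to_m,
    call_mvps,
    fit_moderated_t,
    group_delta,
    m_to_beta,
    memory_delta,
    motif_effect_summary,
    trigamma_inverse,
)

from conftest import toy_m_matrix

# frozen reference values for toy_m_matrix() (5 vs 5 design, group A - group B)
REF_D0 = 2.8405377741
REF_S02 = 0.414459623535
REF_T = [-1.234398148, -2.247146548, 1.450323127, -2.001967359, -2.765386853,
         0.6340721098, 1.860223776, -0.3816385481, 2.071586869, -1.41746779,
         4.407323182, -2.243513733, -0.7248588497, -4.159707198, 1.737152561,
         4.105678853, 1.090935351, -4.192244992, -2.446653921, 2.4298181]
REF_P = [0.2431437938, 0.04645618863, 0.1752789402, 0.07094515047, 0.01860559555,
         0.5391829323, 0.09017769788, 0.7101039925, 0.06296970863, 0.1844418755,
         0.001087627401, 0.04675149495, 0.4838910077, 0.00164029253, 0.1106470533,
         0.001796006398, 0.2989553654, 0.001553380407, 0.03273246631, 0.03371879328]
REF_S2 = [0.298882532, 0.5113042887, 1.171762189, 0.5573331781, 0.02778785531,
          1.381017072, 1.231188128, 0.9480753024, 0.1335953453, 0.9474080386,
          0.3512560485, 1.798956544, 1.232999189, 0.7543584184, 0.7757556729,
          0.2244576891, 0.801236417, 0.05431012008, 1.932154184, 0.8577268338]

TOY_GROUPS = {f"A{i}": "HDC" for i in range(5)} | {f"B{i}": "LDC" for i in range(5)}


class TestBetaToM:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        out = beta_to_m(pd.DataFrame([[beta]]))
        assert out.iloc[0, 0] == pytest.approx(m, abs=1e-12)

    def test_roundtrip_on_interior(self):
        rng = np.random.default_rng(0)
        b = pd.DataFrame(rng.uniform(0.01, 0.99, size=(50, 4)))
        back = m_to_beta(beta_to_m(b))
        np.testing.assert_allclose(back.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_boundaries_clamped_finite(self):
        out = beta_to_m(pd.DataFrame([[0.0, 1.0]]))
        assert np.isfinite(out.to_numpy()).all()


class TestModeratedT:
    def test_matches_reference_implementation_to_1e6(self):
        table = fit_moderated_t(toy_m_matrix(), TOY_GROUPS)
        assert table.d0 == pytest.approx(REF_D0, abs=1e-6)
        assert table.s02 == pytest.approx(REF_S02, abs=1e-6)
        np.testing.assert_allclose(table.frame["t"], REF_T, atol=1e-6)
        np.testing.assert_allclose(table.frame["p"], REF_P, atol=1e-6)
        np.testing.assert_allclose(table.frame["s2"], REF_S2, atol=1e-6)

    def test_prior_df_infinite_limit_uses_prior_variance(self):
        m = toy_m_matrix()
        table = fit_moderated_t(m, TOY_GROUPS, d0_override=np.inf)
        x1 = m[[f"A{i}" for i in range(5)]].mean(axis=1)
        x2 = m[[f"B{i}" for i in range(5)]].mean(axis=1)
        expected = (x1 - x2) / np.sqrt(table.s02 * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(table.frame["t"], expected, atol=1e-10)

    def test_prior_df_zero_limit_is_ordinary_t(self):
        from scipy import stats

        m = toy_m_matrix()
        table = fit_moderated_t(m, TOY_GROUPS, d0_override=0.0)
        a = m[[f"A{i}" for i in range(5)]].to_numpy()
        b = m[[f"B{i}" for i in range(5)]].to_numpy()
        t_ref, _ = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(table.frame["t"], t_ref, atol=1e-10)

    def test_zero_variance_probe_gets_finite_t(self):
        m = toy_m_matrix()
        m.loc["p00"] = [1.0] * 5 + [0.0] * 5  # no within-group variance
        table = fit_moderated_t(m, TOY_GROUPS)
        assert np.isfinite(table.frame.loc["p00", "t"])

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (0.1, 1.0, 5.0, 50.0):
            assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-6)

    def test_cohort_calls_all_cph_hyper(self, mvp_table):
        """At the calibrated effect size, essentially every CpH probe is a
        significant hyper-MVP (HDC above LDC)."""
        frame = mvp_table.frame
        assert (frame["significant"].mean()) >= 0.90
        assert (frame.loc[frame["significant"], "direction"] == "hyper").all()


class TestBenjaminiHochberg:
    def test_hand_computed_qvalues(self):
        from cphcap.mvp import MVPTable

        frame = pd.DataFrame({"p": [0.01, 0.02, 0.03],
                              "delta_beta": [0.1, 0.2, 0.3]},
                             index=["a", "b", "c"])
        out = call_mvps(MVPTable(frame, d0=1.0, s02=1.0), fdr=0.05)
        np.testing.assert_allclose(out.frame["q"], [0.03, 0.03, 0.03], atol=1e-12)
        assert out.frame["significant"].all()

    def test_all_p_one_nothing_significant(self):
        from cphcap.mvp import MVPTable

        frame = pd.DataFrame({"p": [1.0] * 5, "delta_beta": [0.1] * 5})
        out = call_mvps(MVPTable(frame, d0=1.0, s02=1.0))
        assert not out.frame["significant"].any()

    def test_q_monotone_in_p_and_bounded(self):
        from cphcap.mvp import MVPTable

        rng = np.random.default_rng(3)
        frame = pd.DataFrame({"p": rng.uniform(size=200),
                              "delta_beta": rng.normal(size=200)})
        out = call_mvps(MVPTable(frame, d0=1.0, s02=1.0))
        srt = out.frame.sort_values("p")
        assert (srt["q"].diff().dropna() >= -1e-15).all()
        assert (out.frame["q"] <= 1).all()
        assert (out.frame["q"] >= out.frame["p"] - 1e-15).all()

    def test_null_probes_fdr_controlled(self):
        """Across replicated null simulations, the realised false discovery
        proportion stays at or below the nominal 5% level."""
        from cphcap.mvp import MVPTable

        rng = np.random.default_rng(12)
        rejections = 0
        trials = 200
        for _ in range(trials):
            x = rng.normal(size=(100, 10))
            m = pd.DataFrame(x, columns=list(TOY_GROUPS))
            table = call_mvps(fit_moderated_t(m, TOY_GROUPS))
            rejections += int(table.frame["significant"].sum())
        # 100 null probes x 200 trials; FDR<=0.05 bounds expected rejections
        assert rejections / (100 * trials) <= 0.05


class TestGroupDelta:
    def test_identical_groups_give_zero_delta_p_one(self):
        vals = pd.DataFrame({"h1": [0.5], "h2": [0.4], "l1": [0.5], "l2": [0.4]})
        res = group_delta(vals, {"h1": "HDC", "h2": "HDC", "l1": "LDC", "l2": "LDC"})
        assert res.delta == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_welch_oracle(self):
        # HDC lines (0.52, 0.48); LDC lines (0.38, 0.36): delta 0.13
        vals = pd.DataFrame({"h1": [0.52], "h2": [0.48], "l1": [0.38], "l2": [0.36]})
        res = group_delta(vals, {"h1": "HDC", "h2": "HDC", "l1": "LDC", "l2": "LDC"})
        assert res.delta == pytest.approx(0.13, abs=1e-12)
        # sample variances: HDC 8e-4, LDC 2e-4 (n=2 each)
        se = np.sqrt(8e-4 / 2 + 2e-4 / 2)
        assert res.t == pytest.approx(0.13 / se, abs=1e-9)
        df = (4e-4 + 1e-4) ** 2 / ((4e-4) ** 2 / 1 + (1e-4) ** 2 / 1)
        assert res.df == pytest.approx(df, abs=1e-9)

    def test_antisymmetric_under_label_swap(self, cph_lines, line_groups):
        res = group_delta(cph_lines, line_groups)
        swapped = {l: {"HDC": "LDC", "LDC": "HDC"}.get(g, g)
                   for l, g in line_groups.items()}
        res2 = group_delta(cph_lines, swapped)
        assert res2.delta == pytest.approx(-res.delta, abs=1e-12)

    def test_single_line_group_flags_undefined_ci(self):
        vals = pd.DataFrame({"h1": [0.5], "l1": [0.4], "l2": [0.35]})
        res = group_delta(vals, {"h1": "HDC", "l1": "LDC", "l2": "LDC"})
        assert not res.ci_defined


class TestMemoryDelta:
    def test_line_equal_to_donor_gives_zero(self):
        vals = pd.DataFrame({"h1": [0.4, 0.6], "d1": [0.4, 0.6]})
        pairs, summary, _, _ = memory_delta(vals, {"h1": "d1"},
                                            {"h1": "HDC", "d1": "donor"})
        assert pairs.loc[0, "delta"] == pytest.approx(0.0)
        assert summary["HDC"] == pytest.approx(0.0)

    def test_cohort_memory_mirrors_construction(self, default_cohort, line_matrix,
                                                line_groups):
        """HDC lines sit ~42 points above their donors, LDC ~29, and the
        donor-vs-donor contrast is null."""
        cph = default_cohort.annotation.of_context("CpH")
        pairs, summary, donor_res, skipped = memory_delta(
            line_matrix.values.loc[cph], default_cohort.truth.donor_map, line_groups)
        assert skipped == []
        assert summary["HDC"] == pytest.approx(0.42, abs=0.03)
        assert summary["LDC"] == pytest.approx(0.29, abs=0.03)
        assert abs(donor_res.delta) < 0.03
        assert donor_res.p > 0.05

    def test_unmatched_lines_skipped_with_notice(self):
        vals = pd.DataFrame({"h1": [0.5], "h2": [0.6], "d1": [0.1]})
        groups = {"h1": "HDC", "h2": "HDC", "d1": "donor"}
        pairs, _, _, skipped = memory_delta(vals, {"h1": "d1"}, groups)
        assert skipped == ["h2"] and len(pairs) == 1


class TestMotifSummary:
    def _annotation(self, flanks, probes):
        return ProbeAnnotation(pd.DataFrame({
            "probe_id": probes, "context": "CpH", "chromosome": "chr1",
            "position": range(100, 100 + len(probes)), "strand": "+",
            "flank6": flanks}))

    def test_single_motif_equals_global_summary(self):
        from cphcap.mvp import MVPTable

        frame = pd.DataFrame({"delta_beta": [0.1, 0.2, 0.3, 0.2, 0.1],
                              "p": [0.01] * 5}, index=[f"p{i}" for i in range(5)])
        ann = self._annotation(["AACAGT"] * 5, list(frame.index))
        out = motif_effect_summary(MVPTable(frame, 1.0, 1.0), ann, min_n=5)
        assert list(out.index) == ["AACAGT"]
        assert out.loc["AACAGT", "mean_delta_beta"] == pytest.approx(0.18)
        assert out.loc["AACAGT", "n"] == 5

    def test_rare_motifs_pooled(self):
        from cphcap.mvp import MVPTable

        frame = pd.DataFrame({"delta_beta": [0.1] * 7, "p": [0.01] * 7},
                             index=[f"p{i}" for i in range(7)])
        ann = self._annotation(["AACAGT"] * 5 + ["TTCTAA", "GGCCAA"], list(frame.index))
        out = motif_effect_summary(MVPTable(frame, 1.0, 1.0), ann, min_n=5)
        assert set(out.index) == {"AACAGT", "other"}
        assert out.loc["other", "n"] == 2

    def test_empty_flanks_rejected(self):
        from cphcap.mvp import MVPTable

        frame = pd.DataFrame({"delta_beta": [0.1], "p": [0.01]}, index=["p0"])
        ann = self._annotation([""], ["p0"])
        with pytest.raises(ValueError):
            motif_effect_summary(MVPTable(frame, 1.0, 1.0), ann)

    def test_effect_independent_of_motif_on_cohort(self, mvp_table, default_cohort):
        """The generator draws flanks independently of effects, so per-motif
        mean effects agree and every motif is uniformly hyper-directional."""
        out = motif_effect_summary(mvp_table, default_cohort.annotation, min_n=5)
        named = out.drop(index="other", errors="ignore")
        assert (named["fraction_hyper"] == 1.0).all()
        # coarse grouping (first flank base, ~670 probes each) pins the
        # motif-independence down tightly
        ann = default_cohort.annotation.frame.set_index("probe_id")
        first = ann["flank6"].reindex(mvp_table.frame.index).str[0]
        by_first = mvp_table.frame.groupby(first.to_numpy())["delta_beta"].mean()
        assert by_first.max() - by_first.min() < 0.01


class TestParameterRecovery:
    def test_mean_recovered_delta_over_seeds(self):
        """Across generator seeds the mean recovered group difference sits
        within 2 points of the configured 13-point gap (small cohorts keep
        the check fast; per-seed spread shrinks in the mean)."""
        from cphcap.mvp import group_delta as gd
        from cphcap.qc import average_replicates as avg
        from cphcap.synthetic import GeneratorConfig, generate_cohort

        deltas = []
        for seed in range(20):
            cohort = generate_cohort(GeneratorConfig(
                seed=100 + seed, n_cph=400, n_cpg=50, n_rs=5, n_hdc_lines=8,
                n_ldc_lines=6, n_donor_lines=1, extracts_per_line=3,
                n_negative_controls=10))
            lines = avg(cohort.beta, cohort.sheet)
            groups = cohort.sheet.group_of_line().to_dict()
            cph = cohort.annotation.of_context("CpH")
            deltas.append(gd(lines.values.loc[cph], groups).delta)
        assert np.mean(deltas) == pytest.approx(0.13, abs=0.02)
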