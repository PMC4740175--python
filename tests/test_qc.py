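"""Quality-control statistics and filters."""

import numpy as np
import pandas as pd
import pytest

from cphcap.datatypes import (
    BetaMatrix,
    ControlIntensities,
    DetectionMatrix,
    ProbeAnnotation,
    SampleSheet,
    VariantTable,
)
from cphcap.qc import (
    REASON_SEX,
    REASON_VARIANT_3PRIME,
    REASON_VARIANT_TARGET,
    average_replicates,
    conversion_efficiency,
    filter_detection,
    filter_probes,
    flag_replicate_outliers,
    svd_confounder_scan,
)
from cphcap.synthetic import ArtifactSpec, inject_artifacts


def _ci(bic, biu, negatives):
    return ControlIntensities("s", np.asarray(bic, float), np.asarray(biu, float),
                              np.asarray(negatives, float))


class TestConversionEfficiency:
    def test_background_equals_unconverted_gives_100(self):
        assert conversion_efficiency(_ci([5150] * 3, [150] * 3, [150] * 4)) == 100.0

    def test_symmetric_signals_give_50(self):
        assert conversion_efficiency(_ci([2650] * 3, [2650] * 3, [150] * 4)) == 50.0

    def test_scale_invariance(self):
        base = _ci([4000, 4200, 3900], [700, 650, 800], [140, 160, 150])
        scaled = _ci(np.array([4000, 4200, 3900]) * 7.3,
                     np.array([700, 650, 800]) * 7.3,
                     np.array([140, 160, 150]) * 7.3)
        assert conversion_efficiency(base) == pytest.approx(
            conversion_efficiency(scaled), abs=1e-12)

    def test_degenerate_controls_flagged_not_crashed(self):
        assert conversion_efficiency(_ci([100] * 3, [100] * 3, [500] * 3)) is None

    def test_converted_only_signal_is_100(self):
        assert conversion_efficiency(_ci([900] * 3, [50] * 3, [100] * 3)) == 100.0


class TestDetectionFilter:
    def _pair(self, detp_values):
        idx = [f"p{i}" for i in range(len(detp_values))]
        cols = [f"s{j}" for j in range(len(detp_values[0]))]
        beta = BetaMatrix(pd.DataFrame(0.5, index=idx, columns=cols))
        detp = DetectionMatrix(pd.DataFrame(detp_values, index=idx, columns=cols))
        return beta, detp

    def test_all_passing_keeps_everything(self):
        beta, detp = self._pair([[0.001, 0.001], [0.005, 0.0]])
        kept, excluded = filter_detection(beta, detp)
        assert excluded == [] and kept.shape == (2, 2)

    def test_single_failure_excludes_exactly_that_probe(self):
        beta, detp = self._pair([[0.001, 0.5], [0.005, 0.0]])
        kept, excluded = filter_detection(beta, detp)
        assert excluded == ["p0"] and list(kept.probe_ids) == ["p1"]

    def test_exclusions_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        beta, detp = self._pair(rng.uniform(0, 0.2, size=(50, 4)).tolist())
        n_excluded = [len(filter_detection(beta, detp, alpha=a)[1])
                      for a in (0.15, 0.05, 0.01)]
        assert n_excluded[0] <= n_excluded[1] <= n_excluded[2]

    def test_bad_alpha_rejected(self):
        beta, detp = self._pair([[0.001]])
        with pytest.raises(ValueError):
            filter_detection(beta, detp, alpha=1.5)

    def test_injected_failures_recovered_exactly(self, small_cohort):
        art = inject_artifacts(small_cohort, ArtifactSpec(n_failed_probes=10), seed=9)
        _, excluded = filter_detection(art.beta, art.detection)
        assert sorted(excluded) == sorted(art.truth.failed_probes)


def _sheet(samples_lines):
    rows = [{"sample_id": s, "line_id": l, "group": "HDC", "cell_class": "hiPSC",
             "passage": 10, "batch": "B1", "slide": "S1",
             "array_position": "R01C01", "sex": "F"} for s, l in samples_lines]
    return SampleSheet(pd.DataFrame(rows))


class TestReplicateOutliers:
    def test_clean_separation_no_flags(self):
        vals = pd.DataFrame({"a1": [0.03, 0.03], "a2": [0.04, 0.02],
                             "b1": [0.97, 0.96], "b2": [0.96, 0.97]},
                            index=["rs1", "rs2"])
        flagged, skipped = flag_replicate_outliers(
            BetaMatrix(vals), _sheet([("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")]))
        assert flagged == [] and skipped == []

    def test_swapped_extract_flagged(self):
        vals = pd.DataFrame({"a1": [0.03, 0.03], "a2": [0.96, 0.97], "a3": [0.02, 0.04],
                             "b1": [0.97, 0.96], "b2": [0.96, 0.97]},
                            index=["rs1", "rs2"])
        flagged, _ = flag_replicate_outliers(
            BetaMatrix(vals),
            _sheet([("a1", "A"), ("a2", "A"), ("a3", "A"), ("b1", "B"), ("b2", "B")]))
        assert flagged == ["a2"]

    def test_single_extract_lines_skipped(self):
        vals = pd.DataFrame({"a1": [0.1], "b1": [0.9], "b2": [0.9]}, index=["rs1"])
        flagged, skipped = flag_replicate_outliers(
            BetaMatrix(vals), _sheet([("a1", "A"), ("b1", "B"), ("b2", "B")]))
        assert skipped == ["A"] and flagged == []

    def test_injected_outliers_recovered_exactly(self, small_cohort):
        art = inject_artifacts(small_cohort, ArtifactSpec(n_outlier_extracts=2), seed=9)
        rs = art.beta.subset_probes(art.annotation.of_context("rs"))
        flagged, _ = flag_replicate_outliers(rs, art.sheet)
        assert sorted(flagged) == sorted(art.truth.outlier_extracts)

    def test_clean_default_cohort_has_no_false_flags(self, default_cohort):
        rs = default_cohort.beta.subset_probes(default_cohort.annotation.of_context("rs"))
        flagged, _ = flag_replicate_outliers(rs, default_cohort.sheet)
        assert flagged == []


class TestAverageReplicates:
    def test_simple_mean_and_single_extract_identity(self):
        vals = pd.DataFrame({"a1": [0.4], "a2": [0.6], "b1": [0.2]}, index=["p1"])
        sheet = _sheet([("a1", "A"), ("a2", "A"), ("b1", "B")])
        lines = average_replicates(BetaMatrix(vals), sheet)
        assert lines.values.loc["p1", "A"] == pytest.approx(0.5)
        assert lines.values.loc["p1", "B"] == pytest.approx(0.2)

    def test_missing_values_pairwise_complete(self):
        vals = pd.DataFrame({"a1": [0.4, np.nan], "a2": [np.nan, 0.8]}, index=["p1", "p2"])
        lines = average_replicates(BetaMatrix(vals), _sheet([("a1", "A"), ("a2", "A")]))
        assert lines.values.loc["p1", "A"] == pytest.approx(0.4)
        assert lines.values.loc["p2", "A"] == pytest.approx(0.8)

    def test_matches_brute_force_on_cohort(self, default_cohort):
        lines = average_replicates(default_cohort.beta, default_cohort.sheet)
        rng = np.random.default_rng(1)
        line_of = default_cohort.sheet.line_of()
        for probe in rng.choice(default_cohort.beta.probe_ids, 5, replace=False):
            for line_id in rng.choice(lines.sample_ids, 3, replace=False):
                extracts = line_of.index[line_of == line_id]
                expected = default_cohort.beta.values.loc[probe, extracts].mean()
                assert lines.values.loc[probe, line_id] == pytest.approx(expected)

    def test_commutes_with_probe_subsetting(self, small_cohort):
        subset = list(small_cohort.beta.probe_ids[:20])
        a = average_replicates(small_cohort.beta.subset_probes(subset),
                               small_cohort.sheet)
        b = average_replicates(small_cohort.beta, small_cohort.sheet).subset_probes(subset)
        assert a.values.equals(b.values)


class TestFilterProbes:
    def _annotation(self):
        return ProbeAnnotation(pd.DataFrame({
            "probe_id": ["p_auto", "p_x", "p_target", "p_window", "p_far", "p_minus"],
            "context": ["CpH"] * 6,
            "chromosome": ["chr1", "chrX", "chr2", "chr2", "chr2", "chr3"],
            "position": [1000, 1000, 5000, 6000, 7000, 9000],
            "strand": ["+", "+", "+", "+", "+", "-"],
            "flank6": ["AACAGT"] * 6,
        }))

    def _variants(self, positions_chr2=(), positions_chr3=()):
        rows = ([{"chromosome": "chr2", "position": p, "ref": "C", "alt": "T"}
                 for p in positions_chr2]
                + [{"chromosome": "chr3", "position": p, "ref": "C", "alt": "T"}
                   for p in positions_chr3])
        return VariantTable(pd.DataFrame(rows, columns=["chromosome", "position",
                                                        "ref", "alt"]))

    def test_sex_chromosome_excluded(self):
        excluded, _ = filter_probes(self._annotation(), None)
        assert excluded == {"p_x": REASON_SEX}

    def test_variant_at_target_dinucleotide(self):
        _, flagged = filter_probes(self._annotation(), self._variants([5001]))
        assert flagged == {"p_target": [REASON_VARIANT_TARGET]}

    def test_variant_in_extension_window(self):
        # 10 bp downstream of the plus-strand target (positions 6002..6011)
        _, flagged = filter_probes(self._annotation(), self._variants([6011]))
        assert flagged == {"p_window": [REASON_VARIANT_3PRIME]}

    def test_variant_just_outside_window_not_flagged(self):
        _, flagged = filter_probes(self._annotation(), self._variants([7012]))
        assert flagged == {}

    def test_minus_strand_window_upstream(self):
        # minus-strand probe at 9000: target (8999, 9000), window 8989..8998
        _, flagged = filter_probes(self._annotation(), self._variants((), [8995]))
        assert flagged == {"p_minus": [REASON_VARIANT_3PRIME]}


class TestSvdScan:
    def test_constant_covariate_gives_missing_p(self):
        rng = np.random.default_rng(0)
        beta = BetaMatrix(pd.DataFrame(rng.uniform(0.2, 0.8, (30, 6)),
                                       index=[f"p{i}" for i in range(30)],
                                       columns=[f"s{j}" for j in range(6)]))
        sheet = _sheet([(f"s{j}", f"L{j}") for j in range(6)])
        out = svd_confounder_scan(beta, sheet, k=2)
        assert out["batch"].isna().all()  # batch identical for all samples

    def test_component_aligned_covariate_detected(self):
        # two well-separated sample blocks: PC1 splits them; a covariate
        # matching the split must associate far more strongly than one that
        # does not
        rng = np.random.default_rng(1)
        base = rng.uniform(0.3, 0.5, size=(40, 1))
        x = np.repeat(base, 8, axis=1)
        x[:, 4:] += 0.3
        x += rng.normal(0, 1e-4, size=x.shape)  # break exact rank ties
        beta = BetaMatrix(pd.DataFrame(x, index=[f"p{i}" for i in range(40)],
                                       columns=[f"s{j}" for j in range(8)]))
        rows = [{"sample_id": f"s{j}", "line_id": f"L{j}", "group": "HDC",
                 "cell_class": "hiPSC", "passage": 10,
                 "batch": "B1" if j < 4 else "B2",
                 "slide": "S1" if j % 2 == 0 else "S2",
                 "array_position": "R01C01", "sex": "F"} for j in range(8)]
        out = svd_confounder_scan(BetaMatrix(beta.values),
                                 SampleSheet(pd.DataFrame(rows)), k=2)
        # batch exactly reproduces the PC1 sign split, so its p is the
        # smallest Kruskal-Wallis p attainable at 4 vs 4 (rank-determined)
        from scipy import stats
        floor_p = stats.kruskal([1, 2, 3, 4], [5, 6, 7, 8])[1]
        assert out.loc["PC1", "batch"] == pytest.approx(floor_p, abs=1e-12)
        assert out.loc["PC1", "slide"] > 0.1

    def test_no_technical_association_on_randomized_cohort(self, qc_products):
        """Array layout is randomized, so batch/slide/position stay null on
        the leading components of the seeded default cohort."""
        _, _, report = qc_products
        sub = report.svd_associations.loc[["PC1", "PC2", "PC3"],
                                          ["batch", "slide", "array_position"]]
        assert (sub > 0.01).all().all()
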