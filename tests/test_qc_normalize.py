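"""QC flagging thresholds, attenuation correction, log2-RPM normalization,
outlier detection and probe collapse."""
import numpy as np
import pandas as pd
import pytest

from httox import qc_normalize as qn

from conftest import make_probe_counts, make_sheet


@pytest.fixture
def passing_counts():
    # 100 probes x 4 samples, all probes well expressed
    rng = np.random.default_rng(0)
    return make_probe_counts(rng.integers(50, 500, size=(100, 4)))


class TestQCFlag:
    @pytest.mark.parametrize(
        "column,bad_value",
        [
            ("total_reads", 400_000),
            ("aligned_reads", 499_999),
            ("total_alignment_rate", 39.9),
            ("unique_alignment_rate", 29.9),
        ],
    )
    def test_below_threshold_flags(self, passing_counts, column, bad_value):
        sheet = make_sheet(list(passing_counts.samples))
        sheet.loc[0, column] = bad_value
        report = qn.qc_flag(sheet, passing_counts)
        assert report.table["any_fail"].to_list() == [True, False, False, False]
        assert report.table[f"{column}_fail"].iloc[0]

    def test_boundary_values_pass(self, passing_counts):
        """Comparisons are strict 'below': a sample exactly at every threshold
        is not flagged."""
        sheet = make_sheet(list(passing_counts.samples), total_reads=500_000,
                           aligned_reads=500_000, total_rate=40.0, unique_rate=30.0)
        report = qn.qc_flag(sheet, passing_counts)
        assert not report.table["any_fail"].any()

    def test_probe_expression_breadth_from_matrix(self):
        """A sample with 49% of probes at >=5 reads is flagged, 50% passes;
        the criterion is computed from the counts, not the sheet."""
        values = np.full((100, 2), 100)
        values[49:, 0] = 0   # 49% expressed
        values[50:, 1] = 0   # 50% expressed
        pc = make_probe_counts(values)
        sheet = make_sheet(list(pc.samples))
        sheet["pct_probes_expressed"] = 100.0  # sheet says fine; matrix decides
        report = qn.qc_flag(sheet, pc)
        assert report.table["pct_probes_expressed_fail"].to_list() == [True, False]
        assert report.table["pct_probes_expressed"].to_list() == [49.0, 50.0]

    def test_sample_missing_from_sheet_errors(self, passing_counts):
        sheet = make_sheet(list(passing_counts.samples)[:-1])
        with pytest.raises(ValueError, match="missing"):
            qn.qc_flag(sheet, passing_counts)


class TestUnattenuate:
    def test_multiplies_by_factor(self):
        pc = make_probe_counts(np.array([[100], [7], [0]]), factors=[10, 1, 25])
        out = qn.unattenuate(pc)
        assert out.counts.iloc[:, 0].to_list() == [1000, 7, 0]
        assert out.unattenuated

    def test_applies_exactly_once(self):
        pc = make_probe_counts(np.array([[5]]), factors=[2])
        once = qn.unattenuate(pc)
        with pytest.raises(ValueError, match="already"):
            qn.unattenuate(once)

    def test_missing_factor_rejected_at_construction(self):
        manifest = pd.DataFrame(
            {"gene_id": ["g0"], "attenuation_factor": [np.nan]},
            index=pd.Index(["p0"], name="probe_id"),
        )
        with pytest.raises(ValueError, match="attenuation"):
            qn.ProbeCounts(counts=pd.DataFrame([[1]], index=["p0"], columns=["s0"]),
                           manifest=manifest)


class TestNormalize:
    def test_log2_rpm_formula(self):
        """count 9 in a library of 1e6 -> log2(10); count 0 -> 0."""
        values = np.zeros((2, 1), dtype=int)
        values[0, 0] = 9
        values[1, 0] = 1_000_000 - 9
        pc = make_probe_counts(values, unattenuated=True)
        norm = qn.normalize(pc)
        assert norm.values.iloc[0, 0] == pytest.approx(np.log2(10), abs=1e-9)
        zero = make_probe_counts(np.array([[0], [10]]), unattenuated=True)
        assert qn.normalize(zero).values.iloc[0, 0] == 0.0

    def test_rpm_sums_to_million_before_log(self, passing_counts):
        norm = qn.normalize(qn.unattenuate(passing_counts))
        rpm = 2.0**norm.values - norm.pseudocount
        assert np.allclose(rpm.sum(axis=0), 1e6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 1000, size=(50, 2))
        pc1 = qn.normalize(make_probe_counts(base, unattenuated=True))
        pc2 = qn.normalize(make_probe_counts(base * 2, unattenuated=True))
        pd.testing.assert_frame_equal(pc1.values, pc2.values)

    def test_all_zero_sample_errors(self):
        pc = make_probe_counts(np.array([[1, 0], [2, 0]]), unattenuated=True)
        with pytest.raises(ValueError, match="all-zero"):
            qn.normalize(pc)

    def test_requires_unattenuated_flag(self, passing_counts):
        with pytest.raises(ValueError, match="unattenuate"):
            qn.normalize(passing_counts)


class TestDetectOutliers:
    def _norm(self, values, samples):
        pc = make_probe_counts(values, samples=samples, unattenuated=True)
        return qn.normalize(pc)

    def test_identical_replicates_are_clean(self):
        rng = np.random.default_rng(2)
        col = rng.integers(10, 1000, size=200)
        values = np.column_stack([col] * 4) + rng.integers(0, 3, size=(200, 4))
        samples = [f"s{j}" for j in range(4)]
        norm = self._norm(values, samples)
        sheet = make_sheet(samples)
        assert qn.detect_outliers(norm, sheet) == []

    def test_permuted_replicate_is_listed(self):
        rng = np.random.default_rng(3)
        col = rng.integers(10, 5000, size=300)
        values = np.column_stack([col + rng.integers(0, 20, 300) for _ in range(4)])
        values[:, 3] = rng.permutation(values[:, 3])  # destroy correlation
        samples = [f"s{j}" for j in range(4)]
        norm = self._norm(values, samples)
        sheet = make_sheet(samples)
        assert qn.detect_outliers(norm, sheet, r_min=0.8) == ["s3"]

    def test_r_min_of_minus_one_lists_nothing(self):
        rng = np.random.default_rng(4)
        values = rng.integers(1, 100, size=(50, 4))
        samples = [f"s{j}" for j in range(4)]
        norm = self._norm(values, samples)
        assert qn.detect_outliers(norm, make_sheet(samples), r_min=-1.0) == []


class TestCollapseProbes:
    def _norm_df(self, values, manifest):
        return qn.NormalizedExpression(
            values=values, library_sizes=pd.Series(1.0, index=values.columns)
        )

    def test_mean_and_max_policies(self):
        values = pd.DataFrame(
            {"s0": [2.0, 4.0, 7.0]}, index=pd.Index(["p0", "p1", "p2"], name="probe_id")
        )
        manifest = pd.DataFrame(
            {"gene_id": ["gA", "gA", "gB"], "attenuation_factor": 1.0},
            index=values.index,
        )
        norm = self._norm_df(values, manifest)
        mean = qn.collapse_probes(norm, manifest, policy="mean")
        assert mean.values.loc["gA", "s0"] == 3.0
        assert mean.values.loc["gB", "s0"] == 7.0
        mx = qn.collapse_probes(norm, manifest, policy="max")
        assert mx.values.loc["gA", "s0"] == 4.0

    def test_one_probe_per_gene_is_identity(self):
        values = pd.DataFrame({"s0": [1.0, 2.0]}, index=pd.Index(["p0", "p1"], name="probe_id"))
        manifest = pd.DataFrame({"gene_id": ["gA", "gB"], "attenuation_factor": 1.0},
                                index=values.index)
        out = qn.collapse_probes(self._norm_df(values, manifest), manifest)
        assert out.values.to_numpy().tolist() == values.to_numpy().tolist()
        assert out.level == "gene"

    def test_unmapped_probe_excluded(self, caplog):
        values = pd.DataFrame({"s0": [1.0, 2.0]}, index=pd.Index(["p0", "px"], name="probe_id"))
        manifest = pd.DataFrame({"gene_id": ["gA"], "attenuation_factor": 1.0},
                                index=pd.Index(["p0"], name="probe_id"))
        out = qn.collapse_probes(self._norm_df(values, manifest), manifest)
        assert list(out.values.index) == ["gA"]
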