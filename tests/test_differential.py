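"""Fold changes, per-dose ANOVA, BH FDR and DEG counts."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from httox import differential as de

from conftest import make_sheet


def _values_and_sheet(treated: np.ndarray, control: np.ndarray, chemical="CHEM"):
    """Gene x sample frame for one chemical: dose level 1 vs control."""
    n_t, n_c = treated.shape[1], control.shape[1]
    samples = [f"t{j}" for j in range(n_t)] + [f"c{j}" for j in range(n_c)]
    values = pd.DataFrame(
        np.hstack([treated, control]),
        index=[f"g{i:04d}" for i in range(treated.shape[0])],
        columns=samples,
    )
    sheet = make_sheet(samples, chemical=chemical, dose_levels=[1] * n_t + [0] * n_c)
    return values, sheet


class TestFoldChanges:
    def test_identical_groups_give_zero(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 4))
        values, sheet = _values_and_sheet(x, x)
        (prof,) = de.differential_expression(values, sheet)
        assert np.allclose(prof.table["log2fc"], 0.0)

    def test_exact_unit_shift(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(5, 1, size=(20, 4))
        values, sheet = _values_and_sheet(ctrl + 1.0, ctrl)
        (prof,) = de.differential_expression(values, sheet)
        assert np.allclose(prof.table["log2fc"], 1.0)

    def test_planted_effect_recovered_within_tolerance(self):
        """+2 log2 planted shift at per-replicate log2 sd ~0.32 (the
        dispersion-0.05 count-noise scale): estimated log2FC within +-0.5 of
        2 for >=95% of genes."""
        rng = np.random.default_rng(1)
        sd = np.sqrt(0.05) / np.log(2)
        base = rng.normal(8, 1, size=(500, 1))
        ctrl = base + rng.normal(0, sd, size=(500, 4))
        trt = base + 2.0 + rng.normal(0, sd, size=(500, 4))
        values, sheet = _values_and_sheet(trt, ctrl)
        (prof,) = de.differential_expression(values, sheet)
        frac = np.mean(np.abs(prof.table["log2fc"] - 2.0) < 0.5)
        assert frac >= 0.95

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(30, 4)), rng.normal(size=(30, 4))
        v1, s1 = _values_and_sheet(a, b)
        v2, s2 = _values_and_sheet(b, a)
        (p1,) = de.differential_expression(v1, s1)
        (p2,) = de.differential_expression(v2, s2)
        assert np.allclose(p1.table["log2fc"], -p2.table["log2fc"])

    def test_missing_control_errors(self):
        rng = np.random.default_rng(3)
        values, sheet = _values_and_sheet(rng.normal(size=(5, 4)), rng.normal(size=(5, 4)))
        sheet.loc[sheet["dose_level"] == 0, "dose_level"] = 2
        with pytest.raises(ValueError, match="control"):
            de.differential_expression(values, sheet)


class TestAnovaFDR:
    def test_two_group_anova_equals_pooled_t(self):
        """F(1, n-2) = t^2: per-dose ANOVA p must equal the equal-variance
        two-sided t-test p."""
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, size=(200, 4)), rng.normal(0, 1, size=(200, 4))
        values, sheet = _values_and_sheet(a, b)
        (prof,) = de.differential_expression(values, sheet)
        t_p = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
        assert np.allclose(prof.table["p"], t_p, atol=1e-10)

    def test_null_p_values_are_uniform(self):
        """2,000 null genes, identical group distributions: KS test against
        U(0,1) must not reject at alpha=0.01."""
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=(2000, 4))
        b = rng.normal(0, 1, size=(2000, 4))
        values, sheet = _values_and_sheet(a, b)
        (prof,) = de.differential_expression(values, sheet)
        ks = stats.kstest(prof.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_bh_step_up_hand_example(self):
        """p = (.01,.02,.03,.04), m=4 -> all BH q equal 0.04."""
        rng = np.random.default_rng(6)
        # build 4 genes whose two-group t-test p values are exactly those
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)
        # and the pipeline's q column is BH of its p column
        a = rng.normal(0, 1, size=(50, 4)) + np.linspace(0, 2, 50)[:, None]
        b = rng.normal(0, 1, size=(50, 4))
        values, sheet = _values_and_sheet(a, b)
        (prof,) = de.differential_expression(values, sheet)
        assert np.allclose(prof.table["q"],
                           multipletests(prof.table["p"], method="fdr_bh")[1])

    def test_q_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, size=(300, 4)) + rng.choice([0, 1.5], size=(300, 1))
        b = rng.normal(0, 1, size=(300, 4))
        values, sheet = _values_and_sheet(a, b)
        (prof,) = de.differential_expression(values, sheet)
        tab = prof.table.sort_values("p")
        assert (tab["q"] >= tab["p"] - 1e-12).all()
        assert tab["q"].between(0, 1).all()
        assert (np.diff(tab["q"]) >= -1e-12).all()

    def test_zero_variance_gene_p_is_one(self):
        values = pd.DataFrame(
            [[5.0] * 8, [1, 2, 3, 4, 1, 2, 3, 4]],
            index=["flat", "vary"],
            columns=[f"s{j}" for j in range(8)],
        )
        sheet = make_sheet(list(values.columns), dose_levels=[1] * 4 + [0] * 4)
        (prof,) = de.differential_expression(values, sheet)
        assert prof.table.loc["flat", "p"] == 1.0

    def test_across_doses_scope_shares_p_within_chemical(self):
        rng = np.random.default_rng(8)
        samples = [f"s{j}" for j in range(12)]
        values = pd.DataFrame(rng.normal(size=(20, 12)),
                              index=[f"g{i}" for i in range(20)], columns=samples)
        sheet = make_sheet(samples, dose_levels=[0] * 4 + [1] * 4 + [2] * 4)
        profs = de.differential_expression(values, sheet, scope="across_doses")
        assert len(profs) == 2
        assert np.allclose(profs[0].table["p"], profs[1].table["p"])
        f_p = stats.f_oneway(values.iloc[:, :4], values.iloc[:, 4:8],
                             values.iloc[:, 8:], axis=1).pvalue
        assert np.allclose(profs[0].table["p"], f_p)


class TestDegCounts:
    def _profiles(self, q_values):
        table = pd.DataFrame(
            {"log2fc": 0.0, "p": q_values, "q": q_values},
            index=[f"g{i}" for i in range(len(q_values))],
        )
        return [de.FoldChangeProfile("CHEM", 1, 1.0, 4, 4, table)]

    def test_all_q_one_counts_zero(self):
        out = de.deg_counts(self._profiles([1.0] * 5), q_threshold=0.1)
        assert out["n_deg"].to_list() == [0]

    def test_threshold_one_counts_everything_below_one(self):
        out = de.deg_counts(self._profiles([0.2, 0.5, 0.99]), q_threshold=1.0)
        assert out["n_deg"].to_list() == [3]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            de.deg_counts(self._profiles([0.5]), q_threshold=0.0)
        with pytest.raises(ValueError):
            de.deg_counts(self._profiles([0.5]), q_threshold=1.5)

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        profs = self._profiles(list(rng.uniform(size=100)))
        counts = [de.deg_counts(profs, q)["n_deg"].iloc[0] for q in (0.01, 0.05, 0.1, 0.5, 1.0)]
        assert counts == sorted(counts)


def test_null_fdr_control_over_repeated_simulations():
    """Pure-null simulation: the average fraction of genes with q < 0.05
    stays within 0.05 + 3 SE over 200 runs (BH FDR control)."""
    rng = np.random.default_rng(10)
    fracs = []
    for _ in range(200):
        a = rng.normal(0, 1, size=(300, 4))
        b = rng.normal(0, 1, size=(300, 4))
        values, sheet = _values_and_sheet(a, b)
        (prof,) = de.differential_expression(values, sheet)
        fracs.append(float((prof.table["q"] < 0.05).mean()))
    mean = np.mean(fracs)
    se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert mean <= 0.05 + 3 * se
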