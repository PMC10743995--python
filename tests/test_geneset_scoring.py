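"""AFC/AAFC scores and the permutation null, checked against brute-force
enumeration and analytic identities."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from httox import geneset_scoring as gs
from httox.differential import FoldChangeProfile


def _fc(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.Series(values, index=genes, dtype=float)


def _set(genes, set_id="S", group="none"):
    return gs.GeneSet(set_id=set_id, description=f"group={group}", genes=tuple(genes),
                      phenotype_group=group)


class TestScores:
    def test_worked_example(self):
        """Members with log2FC (1, -2): AFC = -1 (signed sum), AAFC = 3."""
        fc = _fc([1.0, -2.0, 0.5], ["a", "b", "c"])
        s = _set(["a", "b"])
        assert gs.afc_score(fc, s) == -1.0
        assert gs.aafc_score(fc, s) == 3.0

    def test_zero_members_score_zero(self):
        fc = _fc([0.0, 0.0], ["a", "b"])
        assert gs.afc_score(fc, _set(["a", "b"])) == 0.0
        assert gs.aafc_score(fc, _set(["a", "b"])) == 0.0

    def test_duplicate_members_not_double_counted(self):
        fc = _fc([1.0, -2.0], ["a", "b"])
        assert gs.afc_score(fc, _set(["a", "b", "a", "b"])) == -1.0

    def test_absent_members_skipped(self):
        fc = _fc([2.0], ["a"])
        assert gs.afc_score(fc, _set(["a", "zz"])) == 2.0
        with pytest.raises(ValueError, match="no member"):
            gs.afc_score(fc, _set(["zz"]))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=20))
    def test_aafc_dominates_abs_afc(self, values):
        fc = _fc(values)
        s = _set(list(fc.index))
        assert gs.aafc_score(fc, s) >= abs(gs.afc_score(fc, s)) - 1e-9

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=12),
           st.integers(0, 2**31 - 1))
    def test_aafc_invariant_under_sign_flips(self, values, flip_seed):
        rng = np.random.default_rng(flip_seed)
        signs = rng.choice([-1.0, 1.0], size=len(values))
        fc = _fc(values)
        flipped = _fc(list(np.asarray(values) * signs))
        s = _set(list(fc.index))
        assert gs.aafc_score(flipped, s) == pytest.approx(gs.aafc_score(fc, s))
        assert gs.afc_score(_fc(list(-np.asarray(values))), s) == pytest.approx(
            -gs.afc_score(fc, s))


def enumerate_exact_p(values: np.ndarray, m: int, actual: float) -> float:
    """Brute-force upper-tail p over all C(n, m) subsets (AAFC)."""
    values = np.abs(values)
    sums = [sum(c) for c in itertools.combinations(values, m)]
    return sum(s >= actual - 1e-12 for s in sums) / len(sums)


class TestPermutationNull:
    def test_empirical_p_matches_enumeration_oracle(self):
        """Six genes with |FC| 5..0, module = top two: exact p is 1/15; the
        10,000-draw empirical p must sit within 3 binomial SE."""
        fc = _fc([5, 4, 3, 2, 1, 0])
        top2 = _set(["g0", "g1"])
        exact = enumerate_exact_p(fc.to_numpy(), 2, 9.0)
        assert exact == pytest.approx(1 / 15)
        score = gs.permutation_null(fc, top2, method="aafc", n_perm=10_000, seed=42)
        se = math.sqrt(exact * (1 - exact) / 10_000)
        assert abs(score.p - exact) <= 3 * se
        assert score.score == 9.0

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_oracle_equivalence_on_small_universes(self, m):
        rng = np.random.default_rng(m)
        values = rng.normal(0, 2, size=9)
        fc = _fc(list(values))
        s = _set(list(fc.index[:m]))
        actual = float(np.abs(values[:m]).sum())
        exact = enumerate_exact_p(values, m, actual)
        score = gs.permutation_null(fc, s, method="aafc", n_perm=10_000, seed=7)
        se = math.sqrt(exact * (1 - exact) / 10_000) + 1e-9
        assert abs(score.p - exact) <= 3 * se + 2 / 10_000

    def test_degenerate_set_equals_universe(self):
        fc = _fc([1.0, -2.0, 3.0])
        score = gs.permutation_null(fc, _set(list(fc.index)), method="aafc",
                                    n_perm=200, seed=0)
        assert score.p == 1.0
        assert math.isnan(score.z)
        assert score.null_sd == 0.0

    def test_universe_order_does_not_matter(self):
        rng = np.random.default_rng(11)
        vals = list(rng.normal(size=40))
        genes = [f"g{i:02d}" for i in range(40)]
        fc = _fc(vals, genes)
        perm = rng.permutation(40)
        fc_shuffled = fc.iloc[perm]
        s = _set(genes[:5])
        a = gs.permutation_null(fc, s, n_perm=500, seed=3)
        b = gs.permutation_null(fc_shuffled, s, n_perm=500, seed=3)
        assert a.p == b.p and a.null_mean == b.null_mean and a.z == b.z

    def test_p_never_zero(self):
        fc = _fc(list(np.arange(30.0)))
        s = _set([f"g{i}" for i in range(25, 30)])  # extreme set
        score = gs.permutation_null(fc, s, method="aafc", n_perm=100, seed=1)
        assert score.p >= 1 / 101

    def test_absent_members_dropped_and_fully_absent_rejected(self):
        fc = _fc([1.0, 2.0])
        # members outside the measured universe are dropped, not drawn
        score = gs.permutation_null(fc, _set(["g0", "zz"]), n_perm=10, seed=0)
        assert score.n_members_used == 1
        with pytest.raises(ValueError, match="no member"):
            gs.permutation_null(fc, _set(["zz", "q"]), n_perm=10, seed=0)


class TestNullCalibration:
    def test_z_is_standard_normal_under_null(self):
        """1,000 random decoy sets on iid-noise FC: mean z near 0, sd near 1,
        empirical p uniform (KS at alpha=0.01)."""
        rng = np.random.default_rng(99)
        universe = [f"g{i:04d}" for i in range(1000)]
        fc = _fc(list(rng.normal(0, 0.3, size=1000)), universe)
        zs, ps = [], []
        for i in range(1000):
            size = int(rng.integers(10, 51))
            members = rng.choice(universe, size=size, replace=False)
            s = _set(list(members), set_id=f"d{i}")
            score = gs.permutation_null(fc, s, method="aafc", n_perm=1000, seed=1000 + i)
            zs.append(score.z)
            ps.append(score.p)
        from scipy import stats

        assert abs(np.mean(zs)) < 0.1
        assert abs(np.std(zs) - 1) < 0.15
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestScoreAll:
    def _profiles(self, rng, n_genes=200, chems=("A", "B"), doses=(1, 2)):
        genes = [f"g{i:03d}" for i in range(n_genes)]
        out = []
        for c in chems:
            for d in doses:
                table = pd.DataFrame({"log2fc": rng.normal(size=n_genes),
                                      "p": 0.5, "q": 0.5}, index=genes)
                out.append(FoldChangeProfile(c, d, float(d), 4, 4, table))
        return out

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        profiles = self._profiles(rng)
        sets = [_set([f"g{i:03d}" for i in range(10)], "s1"),
                _set([f"g{i:03d}" for i in range(20, 35)], "s2")]
        a = gs.score_all(profiles, sets, n_perm=300, seed=17)
        b = gs.score_all(profiles, sets, n_perm=300, seed=17)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_sets_get_identical_nulls(self):
        """Equal-size sets share null draws within a profile, so two sets with
        the same members score identically."""
        rng = np.random.default_rng(6)
        profiles = self._profiles(rng, doses=(1,))
        members = [f"g{i:03d}" for i in range(12)]
        a_b = gs.score_all(profiles, [_set(members, "first"), _set(members, "second")],
                           n_perm=300, seed=2)
        first = a_b[a_b["set_id"] == "first"].drop(columns="set_id").reset_index(drop=True)
        second = a_b[a_b["set_id"] == "second"].drop(columns="set_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(first, second)

    def test_one_row_per_set_chemical_dose(self):
        rng = np.random.default_rng(7)
        profiles = self._profiles(rng)
        sets = [_set([f"g{i:03d}" for i in range(8)], "s1", group="inflammation")]
        table = gs.score_all(profiles, sets, n_perm=100, seed=0)
        assert len(table) == 4
        assert set(table["phenotype_group"]) == {"inflammation"}
        assert table["p"].between(1 / 101, 1).all()
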