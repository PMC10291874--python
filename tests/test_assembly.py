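"""Null-model components: betaMNTD, betaNTI, Raup-Crick, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamcom.assembly import (
    AssemblyConfig,
    PROCESSES,
    assembly_pipeline,
    beta_mntd,
    bnti,
    classify_process,
    partition_processes,
    raup_crick_bray,
)
from streamcom.containers import CountTable, Phylogeny
from streamcom.simulate import simulate_tree


def _table(rows, taxa, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return CountTable(pd.DataFrame(rows, index=ids, columns=taxa))


def brute_force_bmntd(fa, fb, d, weighted):
    """Literal double-loop transcription of the definition."""
    ia = [i for i, v in enumerate(fa) if v > 0]
    ib = [j for j, v in enumerate(fb) if v > 0]
    wa = [fa[i] / sum(fa[i] for i in ia) for i in ia] if weighted else [1 / len(ia)] * len(ia)
    wb = [fb[j] / sum(fb[j] for j in ib) for j in ib] if weighted else [1 / len(ib)] * len(ib)
    part_a = sum(w * min(d[i][j] for j in ib) for w, i in zip(wa, ia))
    part_b = sum(w * min(d[j][i] for i in ia) for w, j in zip(wb, ib))
    return 0.5 * (part_a + part_b)


class TestBetaMntd:
    def test_identical_samples_zero(self, toy_tree):
        t = _table([[3, 1, 0, 2], [3, 1, 0, 2]], ["A", "B", "C", "D"])
        assert beta_mntd(t, toy_tree, ("s0", "s1")) == pytest.approx(0.0)

    def test_single_taxon_pair_reduces_to_patristic(self, toy_tree):
        t = _table([[5, 0, 0, 0], [0, 0, 7, 0]], ["A", "B", "C", "D"])
        expected = toy_tree.patristic().loc["A", "C"]
        assert beta_mntd(t, toy_tree, ("s0", "s1")) == pytest.approx(expected)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_on_random_tables(self, weighted):
        rng = np.random.default_rng(0)
        for rep in range(30):
            n_tips = int(rng.integers(4, 13))
            tree = simulate_tree(n_tips, seed=rep)
            taxa = tree.tip_names
            d = tree.patristic().to_numpy()
            rows = rng.integers(0, 6, size=(2, n_tips))
            rows[0, rng.integers(n_tips)] += 1
            rows[1, rng.integers(n_tips)] += 1
            t = _table(rows, taxa)
            got = beta_mntd(t, tree, ("s0", "s1"), weighted=weighted)
            want = brute_force_bmntd(rows[0], rows[1], d, weighted)
            assert got == pytest.approx(want, abs=1e-10)


class TestBnti:
    def test_branch_length_scale_invariance(self):
        tree = simulate_tree(20, seed=1)
        scaled = Phylogeny.from_newick(
            tree.to_newick()
        )  # identical copy, then scale all lengths
        for node in scaled.tree.traverse(include_self=True):
            node.length = (node.length or 0) * 7.5
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 5, size=(2, 20))
        rows[:, 0] += 1
        t = _table(rows, tree.tip_names)
        b1, _, _ = bnti(t, tree, ("s0", "s1"), n_null=199, seed=3)
        b2, _, _ = bnti(t, scaled, ("s0", "s1"), n_null=199, seed=3)
        assert b1 == pytest.approx(b2, abs=1e-9)

    def test_monotone_in_observed_value(self):
        """Holding the null fixed, a larger observed betaMNTD gives a larger z."""
        nulls = np.random.default_rng(0).normal(1.0, 0.2, 999)
        mean, sd = nulls.mean(), nulls.std(ddof=1)
        zs = [(obs - mean) / sd for obs in np.linspace(0.1, 2.0, 15)]
        assert all(a < b for a, b in zip(zs, zs[1:]))

    def test_self_calibration(self):
        """Pairs drawn from the shuffle null give betaNTI ~ (0, 1)."""
        tree = simulate_tree(60, seed=4)
        taxa = tree.tip_names
        rng = np.random.default_rng(5)
        base = np.zeros((2, 60), dtype=int)
        for r in range(2):
            members = rng.choice(60, size=25, replace=False)
            base[r, members] = rng.integers(1, 50, size=25)
        values = []
        for k in range(100):
            perm = rng.permutation(60)
            shuffled = base[:, perm]  # random taxon-tip mapping
            t = _table(shuffled, taxa)
            b, _, _ = bnti(t, tree, ("s0", "s1"), n_null=199, seed=1000 + k)
            values.append(b)
        values = np.asarray(values)
        assert -0.3 <= values.mean() <= 0.3
        assert 0.8 <= values.std(ddof=1) <= 1.2


class TestRaupCrick:
    def test_endpoints(self):
        """RC hits +/-1 when the observed dissimilarity is beyond every null.

        The pool is sized so a disjoint null pair (the only way a null draw
        could tie the observed BC of 1) is combinatorially all but
        impossible, so every null falls strictly below/above the endpoint.
        """
        rng = np.random.default_rng(0)
        n = 21
        taxa = [f"t{i}" for i in range(n)]
        a = np.zeros(n, dtype=int)
        b = np.zeros(n, dtype=int)
        a[:10] = rng.integers(10, 50, 10)
        b[11:21] = rng.integers(10, 50, 10)
        filler = rng.integers(1, 20, size=(4, n))
        t = CountTable(
            pd.DataFrame(
                np.vstack([a, b, filler]),
                index=["a", "b", "f1", "f2", "f3", "f4"],
                columns=taxa,
            )
        )
        assert raup_crick_bray(t, ("a", "b"), n_null=99, seed=1) == pytest.approx(1.0)
        # identical samples: observed BC = 0, surely below the null
        t2 = CountTable(
            pd.DataFrame(
                np.vstack([a, a, filler]),
                index=["a", "b", "f1", "f2", "f3", "f4"],
                columns=taxa,
            )
        )
        assert raup_crick_bray(t2, ("a", "b"), n_null=99, seed=1) == pytest.approx(-1.0)

    def test_self_calibration_mean_near_zero(self):
        """Observed pairs generated by the procedure's own null spread around 0.

        A fixed background table defines the occurrence frequencies and
        regional abundances the procedure will estimate; observed pairs are
        then drawn from exactly that null, so RC should be centered on 0.
        """
        from streamcom.assembly import _null_community

        rng = np.random.default_rng(123)
        n_taxa = 40
        occ0 = rng.uniform(0.2, 1.0, n_taxa)
        reg0 = rng.lognormal(0, 1, n_taxa)
        filler = np.vstack(
            [
                _null_community(rng, occ0, reg0, int(rng.integers(14, 20)), 1000)
                for _ in range(30)
            ]
        ).astype(int)
        occ_emp = (filler > 0).sum(axis=0).astype(float)
        reg_emp = (filler / filler.sum(axis=1, keepdims=True)).sum(axis=0)
        values = []
        for k in range(200):
            a = _null_community(rng, occ_emp, reg_emp, int(rng.integers(14, 20)), 1000)
            b = _null_community(rng, occ_emp, reg_emp, int(rng.integers(14, 20)), 1000)
            t = CountTable(
                pd.DataFrame(
                    np.vstack([a, b, filler]).astype(int),
                    index=["a", "b"] + [f"s{i}" for i in range(30)],
                    columns=[f"t{i}" for i in range(n_taxa)],
                )
            )
            values.append(raup_crick_bray(t, ("a", "b"), n_null=199, seed=k))
        mean = float(np.mean(values))
        assert -0.1 <= mean <= 0.1


class TestClassification:
    @pytest.mark.parametrize(
        "b,rc,expected",
        [
            (-3.1, 0.2, "homogeneous_selection"),
            (2.5, -0.3, "variable_selection"),
            (0.4, 0.97, "dispersal_limitation"),
            (-1.0, -0.99, "homogenizing_dispersal"),
            (1.2, 0.30, "undominated"),
        ],
    )
    def test_worked_examples(self, b, rc, expected):
        assert classify_process(b, rc) == expected

    @given(
        st.floats(min_value=-50, max_value=50, allow_nan=False),
        st.floats(min_value=-1, max_value=1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_total_on_domain(self, b, rc):
        assert classify_process(b, rc) in PROCESSES

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        pairs = pd.DataFrame(
            {
                "process": rng.choice(PROCESSES, size=40),
                "group": rng.choice(["spring", "winter"], size=40),
            }
        )
        frac = partition_processes(pairs, group_by="group")
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-12)

    def test_counting_fraction(self):
        pairs = pd.DataFrame(
            {
                "process": ["variable_selection"] * 3 + ["undominated"] * 7,
                "group": ["g"] * 10,
            }
        )
        frac = partition_processes(pairs, group_by="group")
        assert frac.loc["g", "variable_selection"] == pytest.approx(0.3)


class TestPipeline:
    def test_deterministic_under_seed(self):
        tree = simulate_tree(25, seed=9)
        rng = np.random.default_rng(10)
        rows = rng.integers(0, 20, size=(4, 25))
        rows[:, 0] += 1
        t = _table(rows, tree.tip_names, ids=["s1", "s2", "s3", "s4"])
        meta = pd.DataFrame(
            {"season": ["spring"] * 4}, index=["s1", "s2", "s3", "s4"]
        )
        cfg = AssemblyConfig(n_null=99, seed=11, group_by="season")
        p1, f1 = assembly_pipeline(t, tree, meta, cfg)
        p2, f2 = assembly_pipeline(t, tree, meta, cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(f1, f2)
        assert len(p1) == 6  # all within-season pairs of 4 samples
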