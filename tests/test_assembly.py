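import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rhizoassembly import (
    CountTable,
    assembly_analysis,
    bmntd,
    bnti,
    classify_pair,
    process_fractions,
    rc_bray,
    rc_bray_exact,
    simulate_tree,
    write_count_table,
    write_tree,
)


def _table(rows, taxa, samples=None):
    rows = np.asarray(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    return CountTable(pd.DataFrame(rows, index=samples, columns=taxa))


class TestBmntd:
    def test_identical_communities_are_zero(self, two_clade_tree):
        t = _table([[1, 2, 0, 0], [1, 2, 0, 0]], list("ABCD"))
        assert bmntd(t, two_clade_tree).data[0, 1] == pytest.approx(0.0)

    def test_star_tree_disjoint_communities(self, star_tree):
        # every cross-community nearest-taxon distance is 2h = 3.0
        t = _table([[5, 1, 0, 0], [0, 0, 7, 2]], list("ABCD"))
        assert bmntd(t, star_tree).data[0, 1] == pytest.approx(3.0)

    def test_two_clade_hand_path_sums(self, two_clade_tree):
        t = _table([[1, 1, 0, 0], [0, 0, 1, 1]], list("ABCD"))
        assert bmntd(t, two_clade_tree).data[0, 1] == pytest.approx(4.0)

    def test_missing_taxon_listed_in_error(self, two_clade_tree):
        t = _table([[1, 1], [1, 1]], ["A", "ZZZ"])
        with pytest.raises(ValueError, match="ZZZ"):
            bmntd(t, two_clade_tree)

    def test_symmetry_zero_diagonal_and_column_order_invariance(self, rng):
        tree = simulate_tree(12, seed=4)
        taxa = sorted(t.name for t in tree.tips())
        counts = rng.integers(0, 12, size=(4, 12))
        counts[:, 0] += 1
        t1 = _table(counts, taxa)
        d1 = bmntd(t1, tree)
        assert np.allclose(d1.data, d1.data.T)
        assert np.allclose(np.diag(d1.data), 0.0)
        perm = rng.permutation(12)
        t2 = _table(counts[:, perm], [taxa[i] for i in perm])
        assert np.allclose(bmntd(t2, tree).data, d1.data)

    def test_scales_linearly_with_branch_lengths(self, rng):
        tree = simulate_tree(10, seed=6)
        taxa = sorted(t.name for t in tree.tips())
        counts = rng.integers(0, 10, size=(3, 10)) + 1
        d1 = bmntd(_table(counts, taxa), tree)
        scaled = tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length *= 3.0
        d2 = bmntd(_table(counts, taxa), scaled)
        assert np.allclose(d2.data, 3.0 * d1.data)

    def test_matches_picante_comdistnt(self, tmp_path, rng):
        """R picante::comdistnt (abundance-weighted) as the independent
        oracle for the nearest-taxon turnover computation."""
        tree = simulate_tree(10, seed=7)
        taxa = sorted(t.name for t in tree.tips())
        counts = rng.integers(0, 20, (4, 10))
        counts[0, :5] = 0
        counts[1, 5:] = 0
        counts[:, 0] += 1  # no empty samples
        table = _table(counts, taxa)
        write_count_table(table, tmp_path / "counts.tsv")
        write_tree(tree, tmp_path / "tree.nwk")
        script = textwrap.dedent("""
            suppressMessages(library(picante))
            tree <- read.tree("tree.nwk")
            x <- read.table("counts.tsv", header=TRUE, row.names=1,
                            sep="\\t", check.names=FALSE)
            d <- comdistnt(t(as.matrix(x)), cophenetic(tree),
                           abundance.weighted=TRUE)
            write.csv(as.matrix(d), "ref.csv")
        """)
        (tmp_path / "oracle.R").write_text(script)
        proc = subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path,
                              capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "ref.csv", index_col=0)
        mine = bmntd(table, tree)
        mine_df = pd.DataFrame(mine.data, index=mine.ids, columns=mine.ids)
        assert np.allclose(mine_df.loc[ref.index, ref.columns], ref, atol=1e-10)


class TestBnti:
    def test_identical_communities_degenerate(self, two_clade_tree):
        t = _table([[2, 3, 1, 0], [2, 3, 1, 0]], list("ABCD"))
        z = bnti(t, two_clade_tree, n_null=49, seed=0)
        assert bool(z["degenerate"].iloc[0])
        assert z["bnti"].iloc[0] == 0.0

    def test_star_tree_null_cannot_vary(self, star_tree):
        t = _table([[5, 1, 0, 0], [0, 0, 7, 2]], list("ABCD"))
        z = bnti(t, star_tree, n_null=49, seed=0)
        assert bool(z["degenerate"].iloc[0])

    def test_minimum_null_count(self, two_clade_tree):
        t = _table([[1, 0, 1, 0], [0, 1, 0, 1]], list("ABCD"))
        with pytest.raises(ValueError):
            bnti(t, two_clade_tree, n_null=5)

    def test_deterministic_given_seed(self, drift_dataset):
        table, _, tree, _, _ = drift_dataset
        sub = table.select_samples(table.sample_ids[:4])
        a = bnti(sub, tree, n_null=49, seed=3)
        b = bnti(sub, tree, n_null=49, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestRcBray:
    def test_bounds(self, drift_dataset):
        table = drift_dataset[0]
        sub = table.select_samples(table.sample_ids[:5])
        rc = rc_bray(sub, n_null=99, seed=0)
        assert rc["rc_bray"].between(-1, 1).all()

    def test_identical_dominant_pair_is_nonpositive(self):
        t = _table([[9, 0, 1], [9, 0, 1], [1, 5, 3]], ["a", "b", "c"])
        rc = rc_bray(t, n_null=499, seed=1)
        val = rc.query("sample_i == 's0' and sample_j == 's1'")["rc_bray"].iloc[0]
        assert val <= 0.0

    def test_enumeration_oracle_small_pool(self):
        """Exhaustive enumeration of every null assembly agrees with the
        Monte-Carlo estimate on a 3-taxon pool."""
        t = _table([[2, 0, 0], [0, 2, 0], [1, 1, 0], [0, 0, 2]], ["a", "b", "c"])
        exact = rc_bray_exact(t, "s0", "s1")
        mc = rc_bray(t, n_null=9_999, seed=5)
        val = mc.query("sample_i == 's0' and sample_j == 's1'")["rc_bray"].iloc[0]
        assert val == pytest.approx(exact, abs=0.05)

    def test_deterministic_given_seed(self, small_table):
        a = rc_bray(small_table, n_null=99, seed=11)
        b = rc_bray(small_table, n_null=99, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestClassification:
    @pytest.mark.parametrize(
        "z,rc,expected",
        [
            (2.5, 0.0, "heterogeneous_selection"),
            (-2.5, 0.99, "homogeneous_selection"),  # selection takes precedence
            (1.0, 0.97, "dispersal_limitation"),
            (0.0, -0.99, "homogenizing_dispersal"),
            (1.0, 0.5, "drift"),
            (2.0, 0.5, "drift"),        # threshold itself is stochastic side
            (-2.0, -0.95, "drift"),     # ties at both cuts fall to drift
            (0.0, 0.95, "drift"),
        ],
    )
    def test_five_way_rule(self, z, rc, expected):
        assert classify_pair(z, rc) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(np.nan, 0.0)
        with pytest.raises(ValueError):
            classify_pair(0.0, np.inf)


class TestProcessFractions:
    def _pairs(self, samples, process="drift"):
        rows = []
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                rows.append({"sample_i": a, "sample_j": b, "process": process})
        return pd.DataFrame(rows)

    def test_all_drift(self):
        samples = [f"s{i}" for i in range(4)]
        fr = process_fractions(self._pairs(samples), {s: "g" for s in samples})
        assert fr.loc[0, "drift"] == 1.0
        assert fr.loc[0, "n_pairs"] == 6

    def test_six_samples_give_fifteen_within_pairs(self):
        samples = [f"s{i}" for i in range(6)]
        fr = process_fractions(self._pairs(samples), {s: "g" for s in samples})
        assert fr.loc[0, "n_pairs"] == 15

    def test_fractions_partition_to_one(self, drift_dataset):
        table, meta, tree, _, _ = drift_dataset
        sub = table.select_samples(table.sample_ids[:8])
        pairs = assembly_analysis(sub, tree, n_null_bnti=49, n_null_rc=49, seed=2)
        grouping = (meta["plant"] + "|" + meta["compartment"]).to_dict()
        fr = process_fractions(pairs, grouping)
        from rhizoassembly.assembly import PROCESSES

        assert np.allclose(fr[list(PROCESSES)].sum(axis=1), 1.0)

    def test_between_group_only_is_error(self):
        pairs = pd.DataFrame(
            [{"sample_i": "a", "sample_j": "b", "process": "drift"}]
        )
        with pytest.raises(ValueError):
            process_fractions(pairs, {"a": "g1", "b": "g2"})
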