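import numpy as np
import pandas as pd
import pytest

from dotkit.synteny import (
    OrthologTable,
    all_signed_permutations,
    apply_reversal,
    bfs_distance_table,
    find_wanderers,
    reversal_distance,
    reversal_scenario,
    shared_signed_order,
    syntenic_blocks,
    wanderer_hotspots,
)
from dotkit.synthio import SynthConfig, generate_ortholog_table


def make_table(rows):
    return OrthologTable(pd.DataFrame(
        rows, columns=["gene_id", "species", "element", "scaffold",
                       "position", "strand"]
    ))


def place(g, sp, elem, pos, strand="+"):
    return [g, sp, elem, f"scf_{sp}", pos, strand]


class TestOrthologTable:
    def test_duplicate_position_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_table([place("a", "s1", "F", 1), place("b", "s1", "F", 1)])

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            make_table([place("a", "s1", "F", 1, "?")])

    def test_tsv_roundtrip(self, tmp_path):
        t = make_table([place("a", "s1", "F", 1), place("a", "s2", "A", 3, "-")])
        p = tmp_path / "t.tsv"
        t.write_tsv(p)
        back = OrthologTable.read_tsv(p)
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True), t.data.reset_index(drop=True)
        )


class TestWanderers:
    def test_f_to_other_is_wanderer(self):
        t = make_table([place("a", "s1", "F", 1), place("a", "s2", "A", 1)])
        rep = find_wanderers(t)
        assert list(rep.wanderers["gene_id"]) == ["a"]
        assert rep.wanderers.iloc[0]["from_element"] == "F"
        assert rep.wanderers.iloc[0]["to_element"] == "A"

    def test_f_in_both_not_wanderer(self):
        t = make_table([place("a", "s1", "F", 1), place("a", "s2", "F", 1)])
        assert find_wanderers(t).wanderers.empty

    def test_non_f_move_reported_separately(self):
        t = make_table([place("a", "s1", "D", 1), place("a", "s2", "E", 1)])
        rep = find_wanderers(t)
        assert rep.wanderers.empty
        assert list(rep.other_moves["gene_id"]) == ["a"]

    def test_unplaced_not_wanderer(self):
        t = make_table([
            place("a", "s1", "F", 1), place("b", "s1", "F", 2),
            place("b", "s2", "F", 1),
        ])
        rep = find_wanderers(t)
        assert rep.wanderers.empty
        assert list(rep.unplaced.itertuples(index=False)) == [("a", "s2")]

    def test_needs_two_species(self):
        with pytest.raises(ValueError):
            find_wanderers(make_table([place("a", "s1", "F", 1)]))

    def test_hotspot_windows(self):
        rows = []
        for i in range(25):
            rows.append(place(f"g{i:02d}", "s1", "F", i + 1))
            rows.append(place(f"g{i:02d}", "s2", "A" if i in (3, 4, 5) else "F", i + 1))
        t = make_table(rows)
        rep = find_wanderers(t)
        hs = wanderer_hotspots(rep.wanderers, t, "s1", window_genes=10)
        f_windows = hs[hs["element"] == "F"]
        assert list(f_windows["n_wanderers"]) == [3, 0, 0]


class TestSharedSignedOrder:
    def base_rows(self):
        return [
            place("a", "s1", "F", 1, "+"), place("b", "s1", "F", 2, "+"),
            place("c", "s1", "F", 3, "+"), place("d", "s1", "F", 4, "+"),
        ]

    def test_identical(self):
        rows = self.base_rows() + [
            place("a", "s2", "F", 1, "+"), place("b", "s2", "F", 2, "+"),
            place("c", "s2", "F", 3, "+"), place("d", "s2", "F", 4, "+"),
        ]
        order, ids = shared_signed_order(make_table(rows), "s1", "s2")
        assert order == [1, 2, 3, 4]
        assert ids == ["a", "b", "c", "d"]

    def test_fully_reversed(self):
        rows = self.base_rows() + [
            place("a", "s2", "F", 4, "-"), place("b", "s2", "F", 3, "-"),
            place("c", "s2", "F", 2, "-"), place("d", "s2", "F", 1, "-"),
        ]
        order, _ = shared_signed_order(make_table(rows), "s1", "s2")
        assert order == [-4, -3, -2, -1]

    def test_mixed_example(self):
        # b order: a, c(-), b(-), d  ->  (+1, -3, -2, +4)
        rows = self.base_rows() + [
            place("a", "s2", "F", 1, "+"), place("c", "s2", "F", 2, "-"),
            place("b", "s2", "F", 3, "-"), place("d", "s2", "F", 4, "+"),
        ]
        order, _ = shared_signed_order(make_table(rows), "s1", "s2")
        assert order == [1, -3, -2, 4]

    def test_off_element_genes_dropped(self):
        rows = self.base_rows() + [
            place("a", "s2", "F", 1, "+"), place("b", "s2", "A", 1, "+"),
            place("c", "s2", "F", 2, "+"), place("d", "s2", "F", 3, "+"),
        ]
        order, ids = shared_signed_order(make_table(rows), "s1", "s2")
        assert ids == ["a", "c", "d"]
        assert order == [1, 2, 3]

    def test_too_few_shared(self):
        rows = [place("a", "s1", "F", 1), place("a", "s2", "A", 1)]
        with pytest.raises(ValueError):
            shared_signed_order(make_table(rows), "s1", "s2")


class TestSyntenicBlocks:
    def test_identity_one_block(self):
        blocks, mean = syntenic_blocks(list(range(1, 9)))
        assert len(blocks) == 1 and mean == 8.0

    def test_swap_two_blocks(self):
        blocks, mean = syntenic_blocks([2, 1])
        assert len(blocks) == 2 and mean == 1.0

    def test_mixed_example(self):
        blocks, mean = syntenic_blocks([1, 2, -5, -4, -3, 6])
        assert blocks == [[1, 2], [-5, -4, -3], [6]]
        assert mean == 2.0

    def test_block_breakpoint_bound(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            perm = [int(s * v) for s, v in
                    zip(rng.choice([-1, 1], n), rng.permutation(np.arange(1, n + 1)))]
            blocks, _ = syntenic_blocks(perm)
            assert len(blocks) <= reversal_distance(perm) * 2 + 1


class TestReversalDistance:
    def test_identity_zero(self):
        assert reversal_distance([1, 2, 3, 4]) == 0

    def test_single_flip(self):
        assert reversal_distance([-1]) == 1

    def test_transposed_pair_is_three(self):
        assert reversal_distance([2, 1]) == 3

    def test_invalid_permutation(self):
        with pytest.raises(ValueError):
            reversal_distance([1, 3])
        with pytest.raises(ValueError):
            reversal_distance([1, 1])

    def test_inverse_symmetry(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 10))
            perm = [int(s * v) for s, v in
                    zip(rng.choice([-1, 1], n), rng.permutation(np.arange(1, n + 1)))]
            inv = [0] * n
            for pos, val in enumerate(perm, start=1):
                inv[abs(val) - 1] = pos if val > 0 else -pos
            assert reversal_distance(perm) == reversal_distance(inv)
            assert (reversal_distance(perm) == 0) == (perm == list(range(1, n + 1)))

    def test_exhaustive_n4_vs_bfs(self):
        tab = bfs_distance_table(4)
        for perm in all_signed_permutations(4):
            assert reversal_distance(perm) == tab[perm], perm


class TestReversalScenario:
    def test_identity_empty(self):
        assert reversal_scenario([1, 2, 3]) == []

    def test_single_flip(self):
        assert reversal_scenario([-1]) == [(0, 0)]

    def test_replay_reaches_identity(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 10))
            perm = [int(s * v) for s, v in
                    zip(rng.choice([-1, 1], n), rng.permutation(np.arange(1, n + 1)))]
            scenario = reversal_scenario(perm)
            assert len(scenario) == reversal_distance(perm)
            cur = list(perm)
            for i, j in scenario:
                cur = apply_reversal(cur, i, j)
            assert cur == list(range(1, n + 1))


class TestSynthioIntegration:
    def test_planted_reversals_bounded(self):
        for seed in range(10):
            cfg = SynthConfig(seed=seed, n_genes=20, n_reversals=4)
            table, reversals, _ = generate_ortholog_table(cfg)
            order, _ = shared_signed_order(table, "spA", "spB")
            assert reversal_distance(order) <= 4

    def test_wanderers_recovered(self):
        cfg = SynthConfig(seed=9, n_genes=20, n_reversals=2, n_wanderers=3)
        table, _, wanderers = generate_ortholog_table(cfg)
        rep = find_wanderers(table)
        assert set(rep.wanderers["gene_id"]) == wanderers
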