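"""Synthetic fixtures, read simulation, and accuracy scoring."""

import numpy as np
import pytest
from scipy import stats

from taxomem.classify import ReadAssignment
from taxomem.simulate import (
    CATEGORIES,
    SimParams,
    SimulationError,
    categorize,
    database_level_histogram,
    evaluate,
    make_fixture,
    make_tree,
    plant_shared_block,
    simulate_reads,
)


class TestFixture:
    def test_forced_counts(self):
        tree, db = make_fixture(seed=1, n_records=10, record_len_range=(100, 100))
        assert len(db) == 10
        assert len(tree) == 31  # full binary 4-level tree: 1+2+4+8+16
        assert all(len(r.residues) == 100 for r in db.records)
        assert all(tree.level(r.node_id) == 4 for r in db.records)

    def test_same_seed_identical(self):
        _, a = make_fixture(seed=9, n_records=5)
        _, b = make_fixture(seed=9, n_records=5)
        assert a.records == b.records

    def test_leaf_labels_uniform(self):
        """Chi-square over many label draws against the uniform-leaf model."""
        tree, db = make_fixture(seed=2, n_records=10_000, record_len_range=(10, 10))
        counts = np.bincount([r.node_id for r in db.records], minlength=len(tree))
        leaf_counts = counts[tree.leaves()]
        assert stats.chisquare(leaf_counts).pvalue > 1e-4

    def test_internal_labels_when_requested(self):
        tree, db = make_fixture(seed=3, n_records=300, internal_frac=0.2)
        levels = {tree.level(r.node_id) for r in db.records}
        assert levels - {4}  # some records sit at internal nodes

    def test_zero_branching_rejected(self):
        with pytest.raises(SimulationError):
            make_tree((2, 0, 2, 2))


class TestSimulateReads:
    def test_zero_error_reads_are_exact_substrings(self):
        tree, db = make_fixture(seed=4, n_records=10, record_len_range=(80, 120))
        by_id = {r.seq_id: r for r in db.records}
        for read in simulate_reads(db, SimParams(n_reads=50, read_len=40, seed=1)):
            src = by_id[read.source_seq]
            assert src.residues[read.source_offset : read.source_offset + 40] == read.residues
            assert read.truth_node == src.node_id

    def test_substitution_rate_matches_binomial(self):
        """Mean mismatches per 100-residue read at 5% error ~ Binomial(100, .05)."""
        tree, db = make_fixture(seed=5, n_records=10, record_len_range=(150, 150))
        by_id = {r.seq_id: r for r in db.records}
        params = SimParams(n_reads=10_000, read_len=100, error_rate=0.05, seed=6)
        mismatches = []
        for read in simulate_reads(db, params):
            src = by_id[read.source_seq].residues[read.source_offset : read.source_offset + 100]
            mismatches.append(sum(a != b for a, b in zip(src, read.residues)))
        mean = np.mean(mismatches)
        se = np.sqrt(100 * 0.05 * 0.95 / len(mismatches))
        assert abs(mean - 5.0) < 3 * se

    def test_substituted_symbols_stay_in_alphabet(self):
        tree, db = make_fixture(seed=5, n_records=5, record_len_range=(60, 60))
        for read in simulate_reads(db, SimParams(n_reads=200, read_len=30, error_rate=0.5, seed=2)):
            assert set(read.residues) <= set("ACDEFGHIKLMNPQRSTVWY")

    def test_same_seed_identical(self):
        tree, db = make_fixture(seed=4, n_records=5)
        p = SimParams(n_reads=20, read_len=30, error_rate=0.1, seed=77)
        assert simulate_reads(db, p) == simulate_reads(db, p)

    def test_read_longer_than_every_record_rejected(self):
        tree, db = make_fixture(seed=4, n_records=5, record_len_range=(50, 60))
        with pytest.raises(SimulationError):
            simulate_reads(db, SimParams(n_reads=1, read_len=100))

    def test_invalid_error_rate_rejected(self):
        with pytest.raises(SimulationError):
            SimParams(n_reads=1, error_rate=1.0)


class TestCategorize:
    @pytest.mark.parametrize(
        "assigned,truth,expected",
        [
            ("1.1.1.1", "1.1.1.1", "correct"),
            ("1.1.1", "1.1.1.1", "ancestor"),
            ("1.1", "1.1.1.1", "ancestor"),
            ("R", "1.1.1.1", "root"),
            ("2.1.1.1", "1.1.1.1", "incorrect"),
            ("1.1.1.2", "1.1.1.1", "incorrect"),  # sibling
            ("1.1.1.1", "1.1.1", "incorrect"),  # descendant of truth, not ancestor
            (None, "1.1.1.1", "unassigned"),
        ],
    )
    def test_categories(self, example_tree, assigned, truth, expected):
        a = example_tree.id_of(assigned) if assigned else None
        assert categorize(a, example_tree.id_of(truth), example_tree) == expected


class TestEvaluate:
    def _assign(self, tree, read_id, name, mem=10, tied=1):
        if name is None:
            return ReadAssignment(read_id, "unassigned", None, None, 0, 0)
        return ReadAssignment(read_id, "assigned", tree.id_of(name), tree.level(tree.id_of(name)), mem, tied)

    def test_all_correct(self, example_tree):
        asn = [self._assign(example_tree, f"r{i}", "1.1.1.1") for i in range(4)]
        truths = {f"r{i}": example_tree.id_of("1.1.1.1") for i in range(4)}
        ev = evaluate(asn, truths, example_tree)
        assert ev.fractions["correct"] == 1.0
        assert sum(ev.fractions.values()) == 1.0

    def test_unassigned_merges_into_root_by_default(self, example_tree):
        asn = [self._assign(example_tree, "r0", None)]
        truths = {"r0": example_tree.id_of("1.1.1.1")}
        merged = evaluate(asn, truths, example_tree)
        assert merged.fractions["root"] == 1.0
        kept = evaluate(asn, truths, example_tree, merge_unassigned_into_root=False)
        assert kept.fractions["unassigned"] == 1.0

    def test_fractions_sum_to_one_on_random_inputs(self, example_tree):
        rng = np.random.default_rng(31)
        names = [n.name for n in example_tree] + [None]
        for _ in range(30):
            asn = [
                self._assign(example_tree, f"r{i}", names[int(rng.integers(len(names)))])
                for i in range(50)
            ]
            truths = {
                f"r{i}": int(rng.choice([n.node_id for n in example_tree])) for i in range(50)
            }
            ev = evaluate(asn, truths, example_tree)
            assert abs(sum(ev.fractions.values()) - 1.0) < 1e-12
            assert set(ev.fractions) == set(CATEGORIES)

    def test_id_mismatch_rejected(self, example_tree):
        asn = [self._assign(example_tree, "r0", "1.1.1.1")]
        with pytest.raises(SimulationError):
            evaluate(asn, {"other": example_tree.id_of("1.1.1.1")}, example_tree)

    def test_mem_statistics_over_assigned_reads(self, example_tree):
        asn = [
            self._assign(example_tree, "r0", "1.1.1.1", mem=10, tied=1),
            self._assign(example_tree, "r1", "1.1.1.2", mem=20, tied=3),
            self._assign(example_tree, "r2", None),
        ]
        truths = {f"r{i}": example_tree.id_of("1.1.1.1") for i in range(3)}
        ev = evaluate(asn, truths, example_tree)
        assert ev.mean_mem_length == 15.0
        assert ev.mean_tied_mems == 2.0
        assert ev.level_histogram == {4: 2}


class TestPlantSharedBlock:
    def test_block_written_into_all_subtree_records(self, example_tree):
        _, db = make_fixture(seed=8, n_records=12, record_len_range=(100, 100), branching=(2, 2, 2, 2))
        tree = db.tree
        node = tree.id_of("1.1.1")
        block = "W" * 30
        planted = plant_shared_block(db, tree, node, block, offset=10)
        n_inside = 0
        for rec in planted.records:
            if tree.is_ancestor(node, rec.node_id):
                assert rec.residues[10:40] == block
                n_inside += 1
            else:
                assert block not in rec.residues
        assert n_inside == sum(1 for r in db.records if tree.is_ancestor(node, r.node_id))

    def test_database_level_histogram(self, example_tree):
        _, db = make_fixture(seed=8, n_records=30)
        hist = database_level_histogram(db)
        assert sum(hist.values()) == 30
        assert set(hist) == {4}
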