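"""Interval-union LCA, naive LCA, weights, min-support, evaluation."""

import numpy as np
import pytest

from conftest import random_record, random_three_level_tree
from oracles import brute_force_assign, per_base_coverage

from lrbin.alignment_io import ReadAlignment, ReadRecord
from lrbin.binning import (
    Assignment,
    BinningParams,
    NodeWeights,
    apply_min_support,
    bin_dataset,
    build_partition,
    coverage_of_taxon,
    evaluate_assignments,
    interval_union_assign,
    naive_lca_assign,
    read_weight,
    significant_on_piece,
)
from lrbin.errors import ConfigurationError, EvaluationError, TaxonNotFoundError
from lrbin.simulate import FIG1_TAXA
from lrbin.taxonomy import TaxonNode, TaxonomyTree


def aln(start, end, score, taxon=None, read_length=200, strand="+"):
    return ReadAlignment(
        read_id="r", read_length=read_length, start=start, end=end, strand=strand,
        bit_score=float(score), ref_accession=f"acc_{start}_{end}_{taxon}",
        taxon_id=taxon,
    )


class TestPartition:
    def test_single_alignment(self):
        assert build_partition([aln(0, 80, 1)]) == [(0, 80)]

    def test_overlapping_pair_split_at_every_endpoint(self):
        pieces = build_partition([aln(0, 80, 1), aln(30, 100, 1)])
        assert pieces == [(0, 30), (30, 80), (80, 100)]

    def test_uncovered_gap_omitted(self):
        pieces = build_partition([aln(0, 40, 1), aln(60, 100, 1)])
        assert pieces == [(0, 40), (60, 100)]

    def test_every_alignment_is_exact_union_of_pieces(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            record = random_record(rng, [1])
            pieces = build_partition(record.alignments)
            for a in record.alignments:
                covered = sorted(p for p in pieces if a.start <= p[0] and p[1] <= a.end)
                assert sum(hi - lo for lo, hi in covered) == a.length
                assert covered[0][0] == a.start and covered[-1][1] == a.end


class TestSignificance:
    def test_single_covering_alignment(self):
        a = aln(0, 80, 50)
        assert significant_on_piece([a], (0, 80), 10.0) == [a]

    def test_threshold_boundary_inclusive(self):
        """Scores {100, 91, 89} on one piece with topPercent 10: the
        threshold is 90 and 91 passes while 89 does not."""
        alignments = [aln(0, 80, s) for s in (100, 91, 89)]
        kept = significant_on_piece(alignments, (0, 80), 10.0)
        assert [a.bit_score for a in kept] == [100.0, 91.0]

    def test_top_percent_zero_keeps_only_maximum(self):
        alignments = [aln(0, 80, s) for s in (100, 100, 99)]
        kept = significant_on_piece(alignments, (0, 80), 0.0)
        assert [a.bit_score for a in kept] == [100.0, 100.0]

    def test_partial_overlap_not_covering(self):
        assert significant_on_piece([aln(0, 40, 100)], (30, 50), 10.0) == []


class TestIntervalUnionAssign:
    def test_fig1_read_placed_on_species_a(self, fig1):
        tree, record, _ = fig1
        result = interval_union_assign(record, tree)
        assert result.taxon_id == FIG1_TAXA["A"]

    def test_fig1_shrunk_a_moves_read_to_genus(self, fig1):
        from lrbin.simulate import make_fig1_fixture

        tree, record, _ = make_fig1_fixture(a_interval=(0, 60))
        result = interval_union_assign(record, tree)
        assert result.taxon_id == FIG1_TAXA["P"]

    def test_single_alignment_full_coverage(self, three_node_tree):
        record = ReadRecord("r", 200, [aln(10, 150, 90, taxon=2)])
        result = interval_union_assign(record, three_node_tree)
        assert result.taxon_id == 2

    def test_fifty_fifty_chimera_goes_to_common_ancestor(self, fig1):
        """Equal halves from species in different genera cannot reach the
        80% bar, so the read lands on the family."""
        tree, _, _ = fig1
        record = ReadRecord(
            "r",
            100,
            [
                aln(0, 50, 100, taxon=FIG1_TAXA["A"], read_length=100),
                aln(50, 100, 100, taxon=FIG1_TAXA["H"], read_length=100),
            ],
        )
        result = interval_union_assign(record, tree)
        assert result.taxon_id == FIG1_TAXA["R"]

    def test_unmapped_alignments_widen_the_denominator(self, three_node_tree):
        """An unmapped alignment contributes to the covered portion, which
        can push a mapped taxon below the coverage bar."""
        record = ReadRecord(
            "r", 200, [aln(0, 50, 90, taxon=2), aln(50, 100, 90, taxon=None)]
        )
        result = interval_union_assign(record, three_node_tree)
        # taxon 2 covers only 50% of [0, 100), and so does the root: the
        # read falls back to the most conservative bin, the root
        assert result.taxon_id == 1
        assert result.qualifying_nodes == frozenset()

    def test_no_alignments_unassigned(self, three_node_tree):
        result = interval_union_assign(ReadRecord("r", 200, []), three_node_tree)
        assert result.taxon_id is None

    def test_no_mapped_alignments_unassigned(self, three_node_tree):
        record = ReadRecord("r", 200, [aln(0, 100, 90)])
        assert interval_union_assign(record, three_node_tree).taxon_id is None

    def test_raising_percent_to_cover_moves_unique_assignments_rootward(self):
        """When a single node qualifies, the covering set is a root chain,
        so raising the coverage bar can only move the read to an ancestor.
        (With tied sibling qualifiers the LCA rule can legitimately move
        deeper when one sibling drops out, so those reads are excluded.)"""
        rng = np.random.default_rng(9)
        for _ in range(50):
            tree = random_three_level_tree(rng)
            record = random_record(rng, tree.leaves())
            previous = None
            for ptc in (50.0, 70.0, 80.0, 95.0):
                result = interval_union_assign(
                    record, tree, BinningParams(percent_to_cover=ptc)
                )
                unique = len(result.qualifying_nodes) == 1
                if previous is not None and result.taxon_id is not None:
                    assert tree.is_ancestor_or_equal(result.taxon_id, previous)
                previous = result.taxon_id if unique else None


class TestCoverage:
    @pytest.mark.parametrize(
        "name, expected",
        [("A", 80.0), ("B", 70.0), ("C", 60.0), ("D", 50.0), ("E", 40.0),
         ("F", 35.0), ("G", 30.0), ("H", 20.0), ("P", 100.0), ("Q", 45.0),
         ("R", 100.0), ("root", 100.0)],
    )
    def test_fig1_coverage_values(self, fig1, name, expected):
        tree, record, _ = fig1
        assert coverage_of_taxon(record, tree, BinningParams(), FIG1_TAXA[name]) == expected

    def test_unknown_taxon_rejected(self, fig1):
        tree, record, _ = fig1
        with pytest.raises(TaxonNotFoundError):
            coverage_of_taxon(record, tree, BinningParams(), 999)

    def test_taxon_without_alignments_covers_nothing(self, three_node_tree):
        record = ReadRecord("r", 200, [aln(0, 100, 90, taxon=2)])
        assert coverage_of_taxon(record, three_node_tree, BinningParams(), 3) == 0.0

    def test_interval_union_monotone_toward_root(self, fig1):
        tree, record, _ = fig1
        params = BinningParams()
        for tid in tree:
            if tid == tree.root_id:
                continue
            child_cov = coverage_of_taxon(record, tree, params, tid)
            parent_cov = coverage_of_taxon(record, tree, params, tree.parent(tid))
            assert parent_cov >= child_cov


class TestNaiveLca:
    def test_all_alignments_one_taxon(self, three_node_tree):
        record = ReadRecord("r", 200, [aln(0, 50, 90, 2), aln(100, 150, 85, 2)])
        assert naive_lca_assign(record, three_node_tree).taxon_id == 2

    def test_equal_scores_on_siblings_resolve_to_parent(self, fig1):
        tree, _, _ = fig1
        record = ReadRecord(
            "r", 200, [aln(0, 100, 90, FIG1_TAXA["A"]), aln(0, 100, 90, FIG1_TAXA["B"])]
        )
        assert naive_lca_assign(record, tree).taxon_id == FIG1_TAXA["P"]

    def test_below_band_alignment_ignored(self, fig1):
        """Scores 100 (A) and 85 (B) with topPercent 10: B is below the
        90-bit threshold, so the read goes to A alone."""
        tree, _, _ = fig1
        record = ReadRecord(
            "r", 200, [aln(0, 100, 100, FIG1_TAXA["A"]), aln(0, 100, 85, FIG1_TAXA["B"])]
        )
        assert naive_lca_assign(record, tree).taxon_id == FIG1_TAXA["A"]

    def test_reduces_to_interval_union_on_identical_intervals(self):
        """When all alignments of a read span one identical interval the
        two algorithms agree, across topPercent values."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            tree = random_three_level_tree(rng)
            leaves = tree.leaves()
            n = int(rng.integers(1, 8))
            record = ReadRecord(
                "r", 200,
                [aln(20, 180, float(rng.integers(50, 150)), int(rng.choice(leaves)))
                 for _ in range(n)],
            )
            for top in (0.0, 5.0, 10.0, 20.0):
                params = BinningParams(top_percent=top)
                assert (
                    interval_union_assign(record, tree, params).taxon_id
                    == naive_lca_assign(record, tree, params).taxon_id
                )


class TestOracleEquivalence:
    def test_coverage_and_assignment_match_per_base_oracle(self):
        """On random reads with integer coordinates <= 200 and random
        3-level taxonomies, interval arithmetic agrees exactly with a
        per-base brute-force union computation, and the assignment equals
        an exhaustive qualifying-node search."""
        rng = np.random.default_rng(17)
        params = BinningParams()
        for _ in range(200):
            tree = random_three_level_tree(rng)
            record = random_record(rng, tree.leaves())
            for tid in tree:
                assert coverage_of_taxon(record, tree, params, tid) == pytest.approx(
                    per_base_coverage(record, tree, params.top_percent, tid)
                )
            assert interval_union_assign(record, tree, params).taxon_id == (
                brute_force_assign(record, tree, params.top_percent, params.percent_to_cover)
            )


class TestWeights:
    def test_read_count_mode(self):
        assert read_weight(ReadRecord("r", 120, []), "read_count") == 1.0

    def test_total_length_mode(self):
        assert read_weight(ReadRecord("r", 120, []), "total_length") == 120.0

    def test_aligned_bases_is_union_measure(self):
        record = ReadRecord("r", 200, [aln(0, 80, 1), aln(30, 100, 1)])
        assert read_weight(record, "aligned_bases") == 100.0

    def test_contig_reads_requires_count(self):
        record = ReadRecord("c1", 120, [], contig_read_count=37)
        assert read_weight(record, "contig_reads") == 37.0
        with pytest.raises(ConfigurationError):
            read_weight(ReadRecord("c2", 120, []), "contig_reads")

    def test_bin_dataset_accumulates_and_tracks_unassigned(self, three_node_tree):
        records = [
            ReadRecord("r1", 200, [aln(0, 100, 90, taxon=2)]),
            ReadRecord("r2", 200, [aln(0, 50, 90, taxon=2)]),
            ReadRecord("r3", 200, [aln(0, 30, 90)]),  # unmapped accession
        ]
        assignments, weights = bin_dataset(records, three_node_tree)
        assert weights.weights == {2: 150.0}
        assert weights.total == 150.0
        assert weights.unassigned == 30.0
        assert [a.assigned for a in assignments] == [True, True, False]

    def test_empty_dataset(self, three_node_tree):
        assignments, weights = bin_dataset([], three_node_tree)
        assert assignments == [] and weights.weights == {} and weights.total == 0.0


class TestMinSupport:
    @pytest.fixture
    def chain_tree(self):
        # root(1) - family(2) - genus(3) - two species (4, 5)
        return TaxonomyTree(
            [TaxonNode(1, 1), TaxonNode(2, 1), TaxonNode(3, 2),
             TaxonNode(4, 3), TaxonNode(5, 3)]
        )

    def test_all_above_threshold_unchanged(self, chain_tree):
        weights = NodeWeights({4: 5000.0, 5: 5000.0})
        out = apply_min_support(weights, chain_tree, BinningParams())
        assert out.weights == weights.weights

    def test_default_threshold_pushes_4_keeps_5(self, chain_tree):
        """With total 10000 and the default 0.05% the threshold is 5:
        a node of weight 4 is pushed to its parent (which keeps it when it
        then meets the threshold), weight 5 is kept in place."""
        weights = NodeWeights({4: 4.0, 3: 10.0, 5: 9986.0})
        out = apply_min_support(weights, chain_tree, BinningParams())
        assert 4 not in out.weights
        assert out.weights[3] == 14.0
        weights = NodeWeights({4: 5.0, 5: 9995.0})
        out = apply_min_support(weights, chain_tree, BinningParams())
        assert out.weights[4] == 5.0

    def test_siblings_accumulate_in_parent(self, chain_tree):
        """Two siblings each below threshold push up; their parent then
        meets the threshold with the combined weight."""
        weights = NodeWeights({4: 3.0, 5: 3.0, 1: 9994.0})
        out = apply_min_support(weights, chain_tree, BinningParams())
        assert out.weights[3] == 6.0
        assert 4 not in out.weights and 5 not in out.weights

    def test_cascade_through_empty_ancestors_to_root(self, chain_tree):
        # threshold 5: weight 4 finds no ancestor with enough weight and
        # cascades through genus and family up to the root
        weights = NodeWeights({4: 4.0, 5: 9996.0})
        out = apply_min_support(weights, chain_tree, BinningParams())
        assert out.weights == {5: 9996.0, 1: 4.0}

    def test_total_conserved_on_random_weight_vectors(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            tree = random_three_level_tree(rng)
            ids = list(tree)
            weights = NodeWeights(
                {int(tid): float(rng.integers(0, 50))
                 for tid in rng.choice(ids, size=min(6, len(ids)), replace=False)}
            )
            params = BinningParams(min_support_percent=float(rng.uniform(0, 20)))
            out = apply_min_support(weights, tree, params)
            assert out.total == pytest.approx(weights.total)


class TestEvaluation:
    def test_perfect_assignment(self, fig1):
        tree, _, _ = fig1
        a_id = FIG1_TAXA["A"]
        assignments = [Assignment(f"r{i}", a_id, 1.0) for i in range(4)]
        truth = {f"r{i}": a_id for i in range(4)}
        assert evaluate_assignments(assignments, truth, tree) == (100.0, 100.0)

    def test_ancestor_assignments_leave_precision_denominator(self, fig1):
        """2 correct reads, 1 on an ancestor of truth, 1 on a sibling:
        sensitivity 50%, precision 2/3."""
        tree, _, _ = fig1
        t = FIG1_TAXA
        assignments = [
            Assignment("r1", t["A"], 1.0),
            Assignment("r2", t["A"], 1.0),
            Assignment("r3", t["P"], 1.0),  # ancestor of truth: uninformative
            Assignment("r4", t["B"], 1.0),  # sibling: wrong
        ]
        truth = {r: t["A"] for r in ("r1", "r2", "r3", "r4")}
        sensitivity, precision = evaluate_assignments(assignments, truth, tree)
        assert sensitivity == 50.0
        assert precision == pytest.approx(100.0 * 2 / 3)

    def test_descendant_of_truth_counts_correct(self, fig1):
        """A read assigned below the true taxon (a species under the true
        genus) counts as correctly assigned."""
        tree, _, _ = fig1
        assignments = [Assignment("r1", FIG1_TAXA["A"], 1.0)]
        truth = {"r1": FIG1_TAXA["P"]}
        assert evaluate_assignments(assignments, truth, tree) == (100.0, 100.0)

    def test_unassigned_reads_count_in_neither(self, fig1):
        tree, _, _ = fig1
        assignments = [
            Assignment("r1", FIG1_TAXA["A"], 1.0),
            Assignment("r2", None, 1.0),
        ]
        truth = {"r1": FIG1_TAXA["A"], "r2": FIG1_TAXA["A"]}
        assert evaluate_assignments(assignments, truth, tree) == (50.0, 100.0)

    def test_precision_undefined_when_denominator_empty(self, fig1):
        tree, _, _ = fig1
        assignments = [Assignment("r1", FIG1_TAXA["P"], 1.0)]
        truth = {"r1": FIG1_TAXA["A"]}
        sensitivity, precision = evaluate_assignments(assignments, truth, tree)
        assert sensitivity == 0.0 and precision is None

    def test_read_missing_from_truth_rejected(self, fig1):
        tree, _, _ = fig1
        with pytest.raises(EvaluationError, match="r1"):
            evaluate_assignments([Assignment("r1", FIG1_TAXA["A"], 1.0)], {}, tree)


def test_binning_params_validated():
    with pytest.raises(ConfigurationError):
        BinningParams(percent_to_cover=101.0)
    with pytest.raises(ConfigurationError):
        BinningParams(weight_mode="bogus")
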