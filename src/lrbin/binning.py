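"""Taxonomic binning of long reads: interval-union LCA and baselines.

The short-read ("naive") LCA places a read on the lowest common ancestor
of the taxa carrying its near-best alignments.  That rule implicitly
assumes all alignments compete for the same gene, which fails for long
reads spanning many genes.  The interval-union LCA instead labels every
taxonomy node with the union of read intervals on which it has a
significant alignment (propagated bottom-up by set union) and places the
read on the lowest node whose interval union covers at least
``percent_to_cover`` of the read's covered portion while none of its
children does; if several such nodes exist the read goes to their LCA.

Significance is local: the read is partitioned at every alignment
endpoint into atomic pieces, and on each piece an alignment is
significant when its bit score lies within ``top_percent`` of the best
bit score among alignments covering that piece.

This module also implements dataset-level weight accumulation under the
four reporting weight modes, the minimum-support push-up rule, and the
sensitivity/precision evaluation used for simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignment_io import ReadAlignment, ReadRecord
from .domination import StrongDominationParams, filter_strongly_dominated
from .errors import ConfigurationError, EvaluationError
from .intervals import Interval, IntervalSet
from .taxonomy import TaxonomyTree

WEIGHT_MODES = ("read_count", "total_length", "aligned_bases", "contig_reads")


@dataclass
class BinningParams:
    """User-facing binning parameters, with the standard defaults.

    top_percent:
        Score band (percent below the local best bit score) within which
        an alignment is significant.  Default 10.
    percent_to_cover:
        Fraction of the read's covered portion a node's interval union
        must reach to qualify for assignment.  Default 80.
    min_support_percent:
        Minimum share of total assigned weight a taxon needs to be
        reported; deficits are pushed up to ancestors.  Default 0.05.
    weight_mode:
        How much weight one read contributes: 1 per read, its length,
        its aligned bases (default; down-weights unaligned stretches),
        or the number of reads in an assigned contig.
    min_percent_cover_to_dominate:
        Overlap threshold of the functional dominance rule.  Default 50.
    strong_domination:
        Thresholds of the strong-domination pre-filter (90/90).
    """

    top_percent: float = 10.0
    percent_to_cover: float = 80.0
    min_support_percent: float = 0.05
    weight_mode: str = "aligned_bases"
    min_percent_cover_to_dominate: float = 50.0
    strong_domination: StrongDominationParams = field(default_factory=StrongDominationParams)

    def __post_init__(self) -> None:
        for name in ("top_percent", "percent_to_cover", "min_support_percent",
                     "min_percent_cover_to_dominate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 100.0):
                raise ConfigurationError(f"{name} must be in [0, 100], got {value}")
        if self.weight_mode not in WEIGHT_MODES:
            raise ConfigurationError(
                f"weight_mode must be one of {WEIGHT_MODES}, got {self.weight_mode!r}"
            )


@dataclass
class Assignment:
    """Result of binning one read."""

    read_id: str
    taxon_id: int | None
    weight: float
    qualifying_nodes: frozenset[int] = frozenset()

    @property
    def assigned(self) -> bool:
        return self.taxon_id is not None


@dataclass
class NodeWeights:
    """Per-taxon accumulated weights over a dataset.

    ``total`` covers assigned weight only; weight of unassigned reads is
    tracked separately in ``unassigned`` and excluded from minimum-support
    thresholds.
    """

    weights: dict[int, float] = field(default_factory=dict)
    unassigned: float = 0.0

    @property
    def total(self) -> float:
        return sum(self.weights.values())


# -- interval-union machinery -------------------------------------------


def build_partition(alignments: Sequence[ReadAlignment]) -> list[Interval]:
    """Partition the covered portion of a read into atomic pieces.

    Every alignment start/end becomes a boundary; the returned pieces are
    the consecutive boundary intervals restricted to regions covered by at
    least one alignment, so each alignment interval is an exact union of
    pieces.
    """
    if not alignments:
        return []
    boundaries = sorted({x for a in alignments for x in a.interval})
    covered = IntervalSet(a.interval for a in alignments)
    return [
        (lo, hi)
        for lo, hi in zip(boundaries, boundaries[1:])
        if covered.contains_interval(lo, hi)
    ]


def significant_on_piece(
    alignments: Sequence[ReadAlignment], piece: Interval, top_percent: float
) -> list[ReadAlignment]:
    """Alignments significant on one atomic piece.

    Among the alignments whose interval fully contains the piece, those
    whose bit score is within ``top_percent`` of the best, boundary
    inclusive: ``bit >= (1 - top_percent/100) * best``.
    """
    lo, hi = piece
    covering = [a for a in alignments if a.start <= lo and hi <= a.end]
    if not covering:
        return []
    best = max(a.bit_score for a in covering)
    threshold = (1.0 - top_percent / 100.0) * best
    return [a for a in covering if a.bit_score >= threshold]


def _taxon_interval_sets(
    alignments: Sequence[ReadAlignment], tree: TaxonomyTree, top_percent: float
) -> dict[int, IntervalSet]:
    """Interval union I(t) for every taxonomy node with any significance.

    Direct per-taxon unions come from significant alignments on atomic
    pieces; a post-order traversal then merges each node's union into its
    parent, so I(s) of an inner node is the union over its subtree.
    Only nodes with a non-empty union appear in the result.
    """
    direct: dict[int, list[Interval]] = {}
    for piece in build_partition(alignments):
        for a in significant_on_piece(alignments, piece, top_percent):
            if a.taxon_id is not None:
                direct.setdefault(a.taxon_id, []).append(piece)

    sets: dict[int, IntervalSet] = {t: IntervalSet(p) for t, p in direct.items()}
    if not sets:
        return {}
    # propagate upward along root paths; post_order over the full tree
    # would also work but touching only involved lineages is cheaper
    for tid in tree.post_order():
        if tid == tree.root_id:
            continue
        iset = sets.get(tid)
        if iset:
            parent = tree.parent(tid)
            sets[parent] = sets.get(parent, IntervalSet()) | iset
    return sets


def coverage_of_taxon(
    record: ReadRecord, tree: TaxonomyTree, params: BinningParams, taxon_id: int
) -> float:
    """Percent of the read's covered portion spanned by I(taxon_id).

    The denominator is the union of *all* alignment intervals of the
    read, including alignments with unmapped accessions.
    """
    tree.node(taxon_id)  # raises on unknown id
    denom = record.covered_portion().measure
    if denom == 0:
        return 0.0
    sets = _taxon_interval_sets(record.alignments, tree, params.top_percent)
    iset = sets.get(taxon_id)
    if iset is None:
        return 0.0
    return 100.0 * iset.measure / denom


def interval_union_assign(
    record: ReadRecord, tree: TaxonomyTree, params: BinningParams | None = None
) -> Assignment:
    """Place one read with the interval-union LCA rule.

    A node qualifies when its interval union covers at least
    ``percent_to_cover`` percent of the read's covered portion while none
    of its children does.  Because interval unions only grow toward the
    root, the covering nodes form an ancestor-closed set and the
    qualifying nodes are its minimal elements.  A unique qualifying node
    receives the read; several qualifying nodes resolve to their LCA; a
    read with no taxon-mapped alignment is unassigned.
    """
    if params is None:
        params = BinningParams()
    weight = read_weight(record, params.weight_mode)
    denom = record.covered_portion().measure
    sets = _taxon_interval_sets(record.alignments, tree, params.top_percent)
    if denom == 0 or not sets:
        return Assignment(record.read_id, None, weight)

    needed = (params.percent_to_cover / 100.0) * denom
    covering = {tid for tid, iset in sets.items() if iset.measure >= needed}
    if not covering:
        # possible only when unmapped alignments widen the denominator
        # beyond what any taxon can cover: bin to the root, the most
        # conservative placement, so that any read with a taxon-mapped
        # alignment is assigned somewhere
        return Assignment(record.read_id, tree.root_id, weight)

    qualifying = frozenset(
        tid
        for tid in covering
        if not any(child in covering for child in tree.children(tid))
    )
    taxon = next(iter(qualifying)) if len(qualifying) == 1 else tree.lca(qualifying)
    return Assignment(record.read_id, taxon, weight, qualifying)


def naive_lca_assign(
    record: ReadRecord, tree: TaxonomyTree, params: BinningParams | None = None
) -> Assignment:
    """Short-read baseline: LCA of taxa of the read's near-best alignments.

    Significance is global per read: bit score within ``top_percent`` of
    the read's best bit score.
    """
    if params is None:
        params = BinningParams()
    weight = read_weight(record, params.weight_mode)
    if not record.alignments:
        return Assignment(record.read_id, None, weight)
    best = max(a.bit_score for a in record.alignments)
    threshold = (1.0 - params.top_percent / 100.0) * best
    taxa = {
        a.taxon_id
        for a in record.alignments
        if a.bit_score >= threshold and a.taxon_id is not None
    }
    if not taxa:
        return Assignment(record.read_id, None, weight)
    return Assignment(record.read_id, tree.lca(taxa), weight, frozenset(taxa))


# -- weights and reporting ----------------------------------------------


def read_weight(record: ReadRecord, weight_mode: str = "aligned_bases") -> float:
    """Weight contributed by one read under the given reporting mode."""
    if weight_mode == "read_count":
        return 1.0
    if weight_mode == "total_length":
        return float(record.read_length)
    if weight_mode == "aligned_bases":
        return float(record.covered_portion().measure)
    if weight_mode == "contig_reads":
        if record.contig_read_count is None:
            raise ConfigurationError(
                f"weight mode 'contig_reads' requires a read count for contig "
                f"{record.read_id!r}"
            )
        return float(record.contig_read_count)
    raise ConfigurationError(f"unknown weight mode {weight_mode!r}")


def bin_dataset(
    records: Iterable[ReadRecord],
    tree: TaxonomyTree,
    params: BinningParams | None = None,
    algorithm: str = "interval_union",
    apply_strong_domination: bool = True,
) -> tuple[list[Assignment], NodeWeights]:
    """Bin every read of a dataset and accumulate node weights.

    Applies the strong-domination pre-filter, assigns each read with the
    chosen algorithm, and sums each read's weight onto its assigned
    taxon.  Unassigned weight is tracked separately and excluded from
    ``NodeWeights.total``.
    """
    if params is None:
        params = BinningParams()
    assign = interval_union_assign if algorithm == "interval_union" else naive_lca_assign
    if algorithm not in ("interval_union", "naive"):
        raise ConfigurationError(f"unknown algorithm {algorithm!r}")

    assignments: list[Assignment] = []
    weights = NodeWeights()
    for record in records:
        if apply_strong_domination:
            record = filter_strongly_dominated(record, params.strong_domination)
        result = assign(record, tree, params)
        assignments.append(result)
        if result.taxon_id is None:
            weights.unassigned += result.weight
        else:
            weights.weights[result.taxon_id] = (
                weights.weights.get(result.taxon_id, 0.0) + result.weight
            )
    return assignments, weights


def apply_min_support(
    weights: NodeWeights, tree: TaxonomyTree, params: BinningParams | None = None
) -> NodeWeights:
    """Push weight of under-supported taxa up to their ancestors.

    The threshold is ``min_support_percent`` of the total assigned
    weight.  Nodes are visited in post-order; a node whose accumulated
    weight (its own plus anything pushed into it from below) falls short
    transfers everything to its parent and reports zero.  The root keeps
    whatever reaches it, so total weight is conserved exactly.
    """
    if params is None:
        params = BinningParams()
    threshold = (params.min_support_percent / 100.0) * weights.total
    acc = dict(weights.weights)
    out: dict[int, float] = {}
    for tid in tree.post_order():
        w = acc.pop(tid, 0.0)
        if w == 0.0:
            continue
        if tid != tree.root_id and w < threshold:
            parent = tree.parent(tid)
            acc[parent] = acc.get(parent, 0.0) + w
        else:
            out[tid] = w
    result = NodeWeights(out, weights.unassigned)
    return result


# -- evaluation ----------------------------------------------------------


def evaluate_assignments(
    assignments: Iterable[Assignment],
    truth: Mapping[str, int],
    tree: TaxonomyTree,
) -> tuple[float, float | None]:
    """Binning sensitivity and precision against known truth.

    Sensitivity is the percentage of *all* reads assigned to the correct
    taxon or one of its descendants.  Precision is the percentage of
    correctly assigned reads among the reads binned to any node that is
    not a strict ancestor of the correct taxon; it is ``None`` when that
    denominator is zero.  Unassigned reads count in neither numerator.
    """
    n_reads = 0
    n_correct = 0
    n_informative = 0  # assigned, and not to a strict ancestor of truth
    for a in assignments:
        if a.read_id not in truth:
            raise EvaluationError(f"read {a.read_id!r} missing from truth")
        n_reads += 1
        if a.taxon_id is None:
            continue
        true_taxon = truth[a.read_id]
        correct = tree.is_ancestor_or_equal(true_taxon, a.taxon_id)
        strict_ancestor = (
            a.taxon_id != true_taxon and tree.is_ancestor_or_equal(a.taxon_id, true_taxon)
        )
        if correct:
            n_correct += 1
        if not strict_ancestor:
            n_informative += 1
    if n_reads == 0:
        raise EvaluationError("no assignments to evaluate")
    sensitivity = 100.0 * n_correct / n_reads
    precision = 100.0 * n_correct / n_informative if n_informative else None
    return sensitivity, precision
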