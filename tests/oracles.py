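"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: per-base marking instead of
interval arithmetic, path intersection instead of depth-walking LCA,
round-based fixed points instead of one-pass filters.  None of it shares
code with the package beyond the public data types.
"""

from __future__ import annotations

from lrbin.alignment_io import ReadAlignment, ReadRecord
from lrbin.domination import StrongDominationParams, strongly_dominates
from lrbin.taxonomy import TaxonomyTree


def lca_by_path_intersection(tree: TaxonomyTree, taxa: set[int]) -> int:
    """LCA as the deepest node common to all root paths."""
    paths = [tree.root_path(t) for t in taxa]
    common = set(paths[0]).intersection(*[set(p) for p in paths[1:]])
    return max(common, key=tree.depth)


def per_base_interval_sets(
    record: ReadRecord, tree: TaxonomyTree, top_percent: float
) -> dict[int, set[int]]:
    """I(t) for every node, computed by marking single bases.

    A base is in I(t) for a leaf-level taxon t when some alignment of t
    covering the base scores within top_percent of the best score among
    alignments covering that base; inner nodes take the union over their
    subtrees.
    """
    marks: dict[int, set[int]] = {}
    for x in range(record.read_length):
        covering = [a for a in record.alignments if a.start <= x < a.end]
        if not covering:
            continue
        best = max(a.bit_score for a in covering)
        threshold = (1.0 - top_percent / 100.0) * best
        for a in covering:
            if a.bit_score >= threshold and a.taxon_id is not None:
                marks.setdefault(a.taxon_id, set()).add(x)
    sets: dict[int, set[int]] = {}
    for tid in tree.post_order():
        bases = set(marks.get(tid, set()))
        for child in tree.children(tid):
            bases |= sets.get(child, set())
        if bases:
            sets[tid] = bases
    return sets


def per_base_coverage(
    record: ReadRecord, tree: TaxonomyTree, top_percent: float, taxon_id: int
) -> float:
    covered = {
        x for a in record.alignments for x in range(a.start, a.end)
    }
    if not covered:
        return 0.0
    sets = per_base_interval_sets(record, tree, top_percent)
    return 100.0 * len(sets.get(taxon_id, set())) / len(covered)


def brute_force_assign(
    record: ReadRecord, tree: TaxonomyTree, top_percent: float, percent_to_cover: float
) -> int | None:
    """Assignment by exhaustive search over all taxonomy nodes."""
    covered = {x for a in record.alignments for x in range(a.start, a.end)}
    sets = per_base_interval_sets(record, tree, top_percent)
    if not covered or not sets:
        return None
    needed = (percent_to_cover / 100.0) * len(covered)
    covering = {tid for tid, bases in sets.items() if len(bases) >= needed}
    if not covering:
        return tree.root_id
    qualifying = {
        tid for tid in covering
        if not any(c in covering for c in tree.children(tid))
    }
    if len(qualifying) == 1:
        return next(iter(qualifying))
    return lca_by_path_intersection(tree, qualifying)


def fixed_point_strong_domination(
    alignments: list[ReadAlignment], params: StrongDominationParams
) -> list[ReadAlignment]:
    """Round-based fixed point: each round simultaneously removes every
    alignment strongly dominated by a current survivor; repeat until
    stable."""
    survivors = list(alignments)
    while True:
        removed = [
            b for b in survivors
            if any(strongly_dominates(a, b, params) for a in survivors if a is not b)
        ]
        if not removed:
            return survivors
        survivors = [a for a in survivors if a not in removed]
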