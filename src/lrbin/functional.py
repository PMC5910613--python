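"""Functional binning of long reads from non-dominated alignments.

A long read spans many genes, and each gene typically aligns to the same
homologue in many taxa.  To avoid reporting the same gene once per taxon,
an alignment ``a`` *dominates* an alignment ``b`` when it covers more
than half of the read covered by ``b`` (strict), has a strictly greater
bit score, and lies on the same strand of the read.  The read's
functional classes are the union of classes of its non-dominated
("representative") alignments — a read can belong to many classes at
once.  Optionally, a dominating alignment must also be taxonomically
compatible with the read's taxonomic bin.

The short-read best-hit baseline (highest-scoring *classified*
alignment) is provided for comparison.
"""

from __future__ import annotations

from typing import Mapping

from .alignment_io import ReadAlignment, ReadRecord
from .binning import BinningParams, NodeWeights, read_weight
from .intervals import overlap_length
from .taxonomy import TaxonomyTree


def taxon_compatible(ref_taxon: int, read_taxon: int, tree: TaxonomyTree) -> bool:
    """True iff one taxon lies on the lineage of the other.

    Equal taxa, an ancestor of the read's bin (a family-level reference
    against a species-level bin) and a descendant (a strain below the
    binned species) are all compatible; siblings are not.
    """
    return tree.is_ancestor_or_equal(ref_taxon, read_taxon) or tree.is_ancestor_or_equal(
        read_taxon, ref_taxon
    )


def dominates(
    a: ReadAlignment,
    b: ReadAlignment,
    params: BinningParams | None = None,
    read_taxon: int | None = None,
    tree: TaxonomyTree | None = None,
) -> bool:
    """Functional dominance of alignment ``a`` over ``b``.

    All three clauses are strict: overlap > min_percent_cover_to_dominate
    percent of ``b``, bit score strictly greater, and same read strand.
    When ``read_taxon`` is given, ``a`` must additionally be
    taxon-compatible with the read's bin to dominate anything.
    """
    if params is None:
        params = BinningParams()
    if a.strand != b.strand:
        return False
    if not a.bit_score > b.bit_score:
        return False
    overlap = overlap_length(a.interval, b.interval)
    if not overlap > (params.min_percent_cover_to_dominate / 100.0) * b.length:
        return False
    if read_taxon is not None:
        if tree is None:
            raise ValueError("taxon-compatibility check requires a taxonomy tree")
        if a.taxon_id is None or not taxon_compatible(a.taxon_id, read_taxon, tree):
            return False
    return True


def select_representative_alignments(
    record: ReadRecord,
    params: BinningParams | None = None,
    read_taxon: int | None = None,
    tree: TaxonomyTree | None = None,
) -> list[ReadAlignment]:
    """Alignments of the read not dominated by any other alignment."""
    if params is None:
        params = BinningParams()
    return [
        b
        for b in record.alignments
        if not any(
            dominates(a, b, params, read_taxon, tree)
            for a in record.alignments
            if a is not b
        )
    ]


def assign_functions(
    record: ReadRecord,
    params: BinningParams | None = None,
    read_taxon: int | None = None,
    tree: TaxonomyTree | None = None,
) -> dict[str, frozenset[str]]:
    """Functional classes of a read, per namespace.

    The union over representative alignments of their class sets.  Reads
    whose reference proteins are all unclassified get an empty map.
    """
    out: dict[str, set[str]] = {}
    for a in select_representative_alignments(record, params, read_taxon, tree):
        for namespace, classes in a.classes.items():
            out.setdefault(namespace, set()).update(classes)
    return {ns: frozenset(c) for ns, c in out.items()}


def best_hit_assign(record: ReadRecord, namespace: str) -> frozenset[str] | None:
    """Short-read baseline: classes of the highest-scoring classified hit.

    Only alignments that carry a class in the namespace compete; returns
    ``None`` when there is no classified alignment.
    """
    classified = [a for a in record.alignments if a.classes.get(namespace)]
    if not classified:
        return None
    best = max(classified, key=lambda a: a.bit_score)
    return best.classes[namespace]


def accumulate_class_weights(
    records: list[ReadRecord],
    params: BinningParams | None = None,
    read_taxa: Mapping[str, int] | None = None,
    tree: TaxonomyTree | None = None,
) -> dict[str, NodeWeights]:
    """Per-namespace class weights over a dataset.

    A read contributes its full weight (under the configured weight mode)
    to every class it is binned to; classes are not mutually exclusive.
    Class ids are used as weight keys.
    """
    if params is None:
        params = BinningParams()
    out: dict[str, NodeWeights] = {}
    for record in records:
        read_taxon = read_taxa.get(record.read_id) if read_taxa else None
        weight = read_weight(record, params.weight_mode)
        classes = assign_functions(record, params, read_taxon, tree)
        for namespace, class_ids in classes.items():
            nw = out.setdefault(namespace, NodeWeights(weights={}))
            for class_id in class_ids:
                nw.weights[class_id] = nw.weights.get(class_id, 0.0) + weight
    return out
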