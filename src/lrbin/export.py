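"""GFF3 annotation export, summary tables and the hierarchical color rule.

Annotated reads are exported as GFF3 ``CDS`` features, one per (by
default non-dominated) alignment, so the read can be inspected in any
genome browser.  Internal 0-based half-open coordinates are converted to
GFF3's 1-based inclusive convention at this boundary, and attribute
values are percent-encoded per the GFF3 specification.  Attribute order
is fixed (ID, Target, taxon, then namespaces alphabetically) so output
is byte-reproducible.

The color-class rule resolves which taxon's color an alignment arrow
would take in a read-level visualization: the read's own taxon when the
reference matches it exactly, the child of the read's taxon on the path
down to a more specific reference, and gray for anything less specific
or incompatible.  Only the class resolution is implemented; palettes are
a rendering concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from .alignment_io import ReadRecord
from .binning import BinningParams, NodeWeights
from .errors import ConfigurationError
from .functional import select_representative_alignments, taxon_compatible
from .taxonomy import TaxonomyTree

_GFF3_ESCAPES = {
    "%": "%25",
    ";": "%3B",
    "=": "%3D",
    "&": "%26",
    ",": "%2C",
    "\t": "%09",
    "\n": "%0A",
}


def _encode_attr(value: str) -> str:
    # percent first so later escapes are not double-escaped
    value = value.replace("%", "%25")
    for char, escape in _GFF3_ESCAPES.items():
        if char != "%":
            value = value.replace(char, escape)
    return value


def export_gff3(
    records: Iterable[ReadRecord],
    tree: TaxonomyTree | None = None,
    params: BinningParams | None = None,
    *,
    namespaces: Iterable[str] = (),
    known_namespaces: Iterable[str] | None = None,
    only_representatives: bool = True,
    require_taxon_compatible: bool = False,
    read_taxa: Mapping[str, int] | None = None,
    source: str = "lrbin",
    stream: TextIO | None = None,
) -> str | None:
    """Export alignments of annotated reads as GFF3 CDS items.

    Each exported alignment becomes one feature line with seqid the read
    id, 1-based inclusive coordinates, the bit score in the score column,
    and attributes ``ID``, ``Target`` (the reference accession), ``taxon``
    (the reference taxon name, when resolved) plus one attribute per
    requested classification namespace.

    By default only representative (non-dominated) alignments are
    exported; ``require_taxon_compatible`` additionally drops alignments
    whose reference taxon is incompatible with the read's assigned taxon
    (``read_taxa``).  Returns the text, or writes to ``stream``.
    """
    if params is None:
        params = BinningParams()
    namespaces = sorted(namespaces)
    if known_namespaces is not None:
        unknown = set(namespaces) - set(known_namespaces)
        if unknown:
            raise ConfigurationError(f"unknown classification namespace(s): {sorted(unknown)}")

    lines = ["##gff-version 3"]
    feature_index = 0
    for record in records:
        if only_representatives:
            alignments = select_representative_alignments(record, params)
        else:
            alignments = list(record.alignments)
        read_taxon = read_taxa.get(record.read_id) if read_taxa else None
        for a in alignments:
            if require_taxon_compatible:
                if tree is None:
                    raise ConfigurationError(
                        "taxon-compatible export requires a taxonomy and read taxa"
                    )
                if read_taxon is None or a.taxon_id is None:
                    continue
                if not taxon_compatible(a.taxon_id, read_taxon, tree):
                    continue
            feature_index += 1
            attrs = [f"ID={_encode_attr(f'cds{feature_index}')}",
                     f"Target={_encode_attr(a.ref_accession)}"]
            if a.taxon_id is not None and tree is not None and a.taxon_id in tree:
                name = tree.node(a.taxon_id).name or str(a.taxon_id)
                attrs.append(f"taxon={_encode_attr(name)}")
            for namespace in namespaces:
                classes = a.classes.get(namespace)
                if classes:
                    value = ",".join(_encode_attr(c) for c in sorted(classes))
                    attrs.append(f"{_encode_attr(namespace)}={value}")
            lines.append(
                "\t".join(
                    (
                        a.read_id,
                        source,
                        "CDS",
                        str(a.start + 1),
                        str(a.end),
                        repr(a.bit_score),
                        a.strand,
                        ".",
                        ";".join(attrs),
                    )
                )
            )
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
        return None
    return text


# -- color classes -------------------------------------------------------


@dataclass(frozen=True)
class ColorClass:
    """Which node's color an alignment arrow takes.

    ``kind`` is ``"SELF"`` (reference taxon equals the read's taxon),
    ``"CHILD"`` (reference is a strict descendant; ``child_id`` is the
    child of the read's taxon on the path down to it) or ``"GRAY"``
    (reference is less specific or incompatible).
    """

    kind: str
    child_id: int | None = None


def color_class(ref_taxon: int, read_taxon: int, tree: TaxonomyTree) -> ColorClass:
    """Resolve the hierarchical color class of one alignment."""
    tree.node(ref_taxon)
    tree.node(read_taxon)
    if ref_taxon == read_taxon:
        return ColorClass("SELF")
    if tree.is_ancestor_or_equal(read_taxon, ref_taxon):
        return ColorClass("CHILD", tree.child_on_path(read_taxon, ref_taxon))
    return ColorClass("GRAY")


# -- summaries -----------------------------------------------------------


def write_summary(weights: NodeWeights, tree: TaxonomyTree, stream: TextIO) -> None:
    """Write a taxon weight summary TSV, heaviest taxa first."""
    stream.write("taxon_id\tname\trank\tweight\n")
    items = sorted(weights.weights.items(), key=lambda kv: (-kv[1], kv[0]))
    for taxon_id, weight in items:
        node = tree.node(taxon_id)
        stream.write(f"{taxon_id}\t{node.name}\t{node.rank}\t{weight!r}\n")


def write_assignments(assignments, stream: TextIO) -> None:
    """Write a read -> taxon TSV; unassigned reads get an empty taxon field."""
    stream.write("read_id\ttaxon_id\tweight\n")
    for a in assignments:
        taxon = "" if a.taxon_id is None else str(a.taxon_id)
        stream.write(f"{a.read_id}\t{taxon}\t{a.weight!r}\n")
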