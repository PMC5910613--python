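"""Strong-domination filtering of redundant alignments.

Aligning long reads against a large protein database produces huge
numbers of near-duplicate alignments covering the same read segment.
The strong-domination filter discards an alignment ``b`` when some other
alignment ``a`` of the same read covers most of it (>= 90% of ``b`` by
default) with a markedly better score (0.9 * bitscore(a) > bitscore(b)
by default).  This replicates the filtering stage of MAF-to-archive
conversion, applied here on the in-memory records.

Domination is judged against the *original* alignment set of the read,
not iteratively against survivors: the strict score inequality with a
factor below one forbids mutual domination, so a single pass is
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment_io import ReadAlignment, ReadRecord
from .intervals import overlap_length


@dataclass
class StrongDominationParams:
    """Thresholds for the strong-domination filter (both percentages)."""

    min_percent_cover: float = 90.0
    top_percent_score: float = 90.0
    require_same_strand: bool = False

    def __post_init__(self) -> None:
        for name in ("min_percent_cover", "top_percent_score"):
            value = getattr(self, name)
            if not (0.0 < value <= 100.0):
                raise ValueError(f"{name} must be in (0, 100], got {value}")


def strongly_dominates(
    a: ReadAlignment, b: ReadAlignment, params: StrongDominationParams | None = None
) -> bool:
    """True iff ``a`` strongly dominates ``b``.

    Requires (1) the overlap to cover at least ``min_percent_cover``% of
    ``b`` and (2) ``top_percent_score/100 * bitscore(a) > bitscore(b)``
    (strict, so equal scores never dominate and no alignment dominates
    itself).  Strand is ignored unless ``require_same_strand`` is set;
    the definition itself states no strand condition.
    """
    if params is None:
        params = StrongDominationParams()
    if params.require_same_strand and a.strand != b.strand:
        return False
    overlap = overlap_length(a.interval, b.interval)
    if overlap < (params.min_percent_cover / 100.0) * b.length:
        return False
    return (params.top_percent_score / 100.0) * a.bit_score > b.bit_score


def filter_strongly_dominated(
    record: ReadRecord, params: StrongDominationParams | None = None
) -> ReadRecord:
    """Drop every alignment strongly dominated by *any* alignment of the read.

    The comparison set is the unfiltered input, so the result does not
    depend on processing order; input order is preserved among survivors.
    The per-read maximum-score alignment always survives.
    """
    if params is None:
        params = StrongDominationParams()
    survivors = [
        b
        for b in record.alignments
        if not any(
            strongly_dominates(a, b, params) for a in record.alignments if a is not b
        )
    ]
    return ReadRecord(record.read_id, record.read_length, survivors, record.contig_read_count)
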