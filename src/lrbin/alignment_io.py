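"""Parsing and collation of DNA-to-protein alignments.

Two input dialects are supported:

* the text MAF emitted by frame-shift-aware DNA-to-protein aligners such
  as LAST (reference/protein ``s`` line first, query/read ``s`` line
  second; ``/`` and ``\\`` frame-shift characters tolerated in the
  aligned strings), and
* a plain tab-separated dialect used as the package's intermediate
  format, replacing binary alignment archives.

All coordinates are normalized at the parsing boundary to 0-based,
half-open intervals on the *forward* strand of the read; a strand flag
records which strand the protein alignment lies on.  Aligners report
alignments batched by reference volume, so alignments of one read are
generally not consecutive in the input — :func:`collate_by_read` regroups
them.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

from .errors import AlignmentParseError, ConsistencyError
from .intervals import IntervalSet

logger = logging.getLogger(__name__)


@dataclass
class ReadAlignment:
    """One alignment of a read against a protein reference.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    read; ``strand`` records the read strand the alignment lies on.
    ``frame_shifts`` counts frame-shift characters seen in the aligned
    string and is informational only.
    """

    read_id: str
    read_length: int
    start: int
    end: int
    strand: str
    bit_score: float
    ref_accession: str
    raw_score: float | None = None
    taxon_id: int | None = None
    classes: dict[str, frozenset[str]] = field(default_factory=dict)
    frame_shifts: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= self.read_length):
            raise ValueError(
                f"{self.read_id}: invalid interval [{self.start},{self.end}) "
                f"on read of length {self.read_length}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.read_id}: strand must be '+' or '-'")
        if not math.isfinite(self.bit_score):
            raise ValueError(f"{self.read_id}: bit score must be finite")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadRecord:
    """All alignments of one read (or contig), in input order."""

    read_id: str
    read_length: int
    alignments: list[ReadAlignment] = field(default_factory=list)
    contig_read_count: int | None = None

    def covered_portion(self) -> IntervalSet:
        """Union of all alignment intervals of the read."""
        return IntervalSet(a.interval for a in self.alignments)


@dataclass
class MappingTable:
    """Reference accession -> taxon and accession -> functional classes."""

    taxon_map: dict[str, int] = field(default_factory=dict)
    class_maps: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    @property
    def namespaces(self) -> set[str]:
        return set(self.class_maps)


# -- MAF parsing --------------------------------------------------------

_LAMBDA_RE = re.compile(r"lambda\s*=\s*([0-9.eE+-]+)")
_K_RE = re.compile(r"\bK\s*=\s*([0-9.eE+-]+)")
_SCORE_RE = re.compile(r"score\s*=\s*([0-9.eE+-]+)")


def _parse_s_line(fields: list[str], lineno: int) -> tuple[str, int, int, str, int, str]:
    if len(fields) < 7:
        raise AlignmentParseError("'s' line has fewer than 7 fields", lineno)
    name = fields[1]
    try:
        start = int(fields[2])
        aln_size = int(fields[3])
        seq_size = int(fields[5])
    except ValueError:
        raise AlignmentParseError("non-numeric coordinate on 's' line", lineno) from None
    strand = fields[4]
    if strand not in ("+", "-"):
        raise AlignmentParseError(f"bad strand {strand!r} on 's' line", lineno)
    if aln_size <= 0:
        raise AlignmentParseError("alignment size must be positive", lineno)
    return name, start, aln_size, strand, seq_size, fields[6]


def maf_query_to_forward(start: int, aln_size: int, strand: str, seq_size: int) -> tuple[int, int]:
    """Convert MAF query coordinates to a forward-strand half-open interval.

    MAF reports the start on the aligned strand; for a ``-`` alignment the
    forward-strand interval is ``[seq_size - start - aln_size, seq_size - start)``.
    """
    if strand == "+":
        return start, start + aln_size
    return seq_size - start - aln_size, seq_size - start


def parse_maf(stream: TextIO | str) -> list[ReadAlignment]:
    """Parse a DNA-query-versus-protein-reference MAF text stream.

    Each record is one ``a score=S`` line followed by two ``s`` lines,
    reference first and query second.  When header comment lines supply
    both ``lambda`` and ``K``, raw scores are converted to bit scores as
    ``(lambda * S - ln K) / ln 2``; otherwise the raw score is passed
    through unchanged (with a warning), which keeps score-ratio filters
    meaningful under any monotone score.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    lam: float | None = None
    kappa: float | None = None
    out: list[ReadAlignment] = []
    warned = False

    lines = enumerate(stream, 1)
    for lineno, line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = _LAMBDA_RE.search(line)
            if m:
                lam = float(m.group(1))
            m = _K_RE.search(line)
            if m:
                kappa = float(m.group(1))
            continue
        if not line.startswith("a"):
            raise AlignmentParseError(f"expected 'a' line, got {line.split()[0]!r}", lineno)
        m = _SCORE_RE.search(line)
        if not m:
            raise AlignmentParseError("'a' line without score=", lineno)
        raw = float(m.group(1))

        s_lines: list[tuple[int, list[str]]] = []
        for s_lineno, s_line in lines:
            if not s_line.strip():
                continue
            fields = s_line.split()
            if fields[0] != "s":
                raise AlignmentParseError(
                    "'a' line not followed by two 's' lines", s_lineno
                )
            s_lines.append((s_lineno, fields))
            if len(s_lines) == 2:
                break
        if len(s_lines) != 2:
            raise AlignmentParseError("'a' line not followed by two 's' lines", lineno)

        ref_name, *_ = _parse_s_line(s_lines[0][1], s_lines[0][0])
        q_name, q_start, q_size, q_strand, q_seq_size, q_aln = _parse_s_line(
            s_lines[1][1], s_lines[1][0]
        )
        start, end = maf_query_to_forward(q_start, q_size, q_strand, q_seq_size)

        if lam is not None and kappa is not None:
            bit = (lam * raw - math.log(kappa)) / math.log(2.0)
        else:
            bit = raw
            if not warned:
                logger.warning(
                    "MAF header supplies no lambda/K; using raw scores as bit scores"
                )
                warned = True

        out.append(
            ReadAlignment(
                read_id=q_name,
                read_length=q_seq_size,
                start=start,
                end=end,
                strand=q_strand,
                bit_score=bit,
                raw_score=raw,
                ref_accession=ref_name,
                frame_shifts=q_aln.count("/") + q_aln.count("\\"),
            )
        )
    return out


# -- tabular dialect ----------------------------------------------------

TABULAR_COLUMNS = (
    "read_id",
    "read_length",
    "start",
    "end",
    "strand",
    "bit_score",
    "ref_accession",
    "frame_shifts",
)


def parse_tabular(stream: TextIO | str) -> list[ReadAlignment]:
    """Parse the tab-separated alignment dialect.

    Columns: read_id, read_length, start, end, strand, bit_score,
    ref_accession, frame_shifts (optional, default 0).  ``#`` lines are
    comments.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[ReadAlignment] = []
    for lineno, line in enumerate(stream, 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 7:
            raise AlignmentParseError(
                f"expected >= 7 tab-separated columns, got {len(fields)}", lineno
            )
        try:
            aln = ReadAlignment(
                read_id=fields[0],
                read_length=int(fields[1]),
                start=int(fields[2]),
                end=int(fields[3]),
                strand=fields[4],
                bit_score=float(fields[5]),
                ref_accession=fields[6],
                frame_shifts=int(fields[7]) if len(fields) > 7 and fields[7] else 0,
            )
        except ValueError as exc:
            raise AlignmentParseError(str(exc), lineno) from None
        out.append(aln)
    return out


def write_tabular(alignments: Iterable[ReadAlignment], stream: TextIO) -> None:
    """Write alignments in the tabular dialect (with a comment header)."""
    stream.write("# " + "\t".join(TABULAR_COLUMNS) + "\n")
    for a in alignments:
        stream.write(
            f"{a.read_id}\t{a.read_length}\t{a.start}\t{a.end}\t{a.strand}\t"
            f"{a.bit_score!r}\t{a.ref_accession}\t{a.frame_shifts}\n"
        )


# -- collation and annotation -------------------------------------------


def collate_by_read(alignments: Iterable[ReadAlignment]) -> list[ReadRecord]:
    """Group alignments by read id, preserving first-seen read order.

    Raises :class:`ConsistencyError` if one read id is reported with two
    different read lengths.
    """
    records: dict[str, ReadRecord] = {}
    for a in alignments:
        rec = records.get(a.read_id)
        if rec is None:
            records[a.read_id] = ReadRecord(a.read_id, a.read_length, [a])
        else:
            if rec.read_length != a.read_length:
                raise ConsistencyError(
                    f"read {a.read_id!r} reported with lengths "
                    f"{rec.read_length} and {a.read_length}"
                )
            rec.alignments.append(a)
    return list(records.values())


def attach_annotations(
    records: Iterable[ReadRecord], mapping: MappingTable
) -> list[ReadRecord]:
    """Resolve each alignment's accession to a taxon id and class sets.

    Unmapped accessions are not an error: the alignment is retained with
    empty annotation (it still contributes to the covered portion of the
    read and may be exported).  The number of distinct unmapped accessions
    is logged.
    """
    out: list[ReadRecord] = []
    unmapped: set[str] = set()
    for rec in records:
        new_alignments = []
        for a in rec.alignments:
            taxon = mapping.taxon_map.get(a.ref_accession)
            classes: dict[str, frozenset[str]] = {}
            for namespace, amap in mapping.class_maps.items():
                cls = amap.get(a.ref_accession)
                if cls:
                    classes[namespace] = frozenset(cls)
            if taxon is None and not classes:
                unmapped.add(a.ref_accession)
            new_alignments.append(replace(a, taxon_id=taxon, classes=classes))
        out.append(
            ReadRecord(rec.read_id, rec.read_length, new_alignments, rec.contig_read_count)
        )
    if unmapped:
        logger.info("%d reference accession(s) had no taxon or class mapping", len(unmapped))
    return out


# -- mapping tables ------------------------------------------------------


def parse_taxon_mapping(stream: TextIO | str) -> dict[str, int]:
    """Parse a 2-column TSV ``accession \\t taxon_id``."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: dict[str, int] = {}
    for lineno, line in enumerate(stream, 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise AlignmentParseError("expected accession<TAB>taxon_id", lineno)
        try:
            out[fields[0]] = int(fields[1])
        except ValueError:
            raise AlignmentParseError(f"non-integer taxon id {fields[1]!r}", lineno) from None
    return out


def parse_class_mapping(stream: TextIO | str) -> dict[str, dict[str, frozenset[str]]]:
    """Parse a 3-column TSV ``accession \\t namespace \\t class_id``."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    acc: dict[str, dict[str, set[str]]] = {}
    for lineno, line in enumerate(stream, 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise AlignmentParseError("expected accession<TAB>namespace<TAB>class_id", lineno)
        accession, namespace, class_id = fields[0], fields[1], fields[2]
        acc.setdefault(namespace, {}).setdefault(accession, set()).add(class_id)
    return {
        ns: {a: frozenset(c) for a, c in amap.items()} for ns, amap in acc.items()
    }


def read_mapping_table(
    taxon_stream: TextIO | str | None = None,
    class_stream: TextIO | str | None = None,
) -> MappingTable:
    table = MappingTable()
    if taxon_stream is not None:
        table.taxon_map = parse_taxon_mapping(taxon_stream)
    if class_stream is not None:
        table.class_maps = parse_class_mapping(class_stream)
    return table


def write_taxon_mapping(taxon_map: dict[str, int], stream: TextIO) -> None:
    for accession in sorted(taxon_map):
        stream.write(f"{accession}\t{taxon_map[accession]}\n")


def write_class_mapping(
    class_maps: dict[str, dict[str, frozenset[str]]], stream: TextIO
) -> None:
    for namespace in sorted(class_maps):
        for accession in sorted(class_maps[namespace]):
            for class_id in sorted(class_maps[namespace][accession]):
                stream.write(f"{accession}\t{namespace}\t{class_id}\n")
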