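"""Deterministic synthetic datasets for exercising the binning pipeline.

Two generators are provided.  :func:`make_fig1_fixture` builds the small
worked example used throughout the documentation and tests: eight
hypothetical species A..H split into two genera P and Q under one family
R, and a single read whose eight equal-score alignments cover between
80% (species A) and 20% (species H) of its aligned portion, with the
genus-level interval unions of P and R both covering 100%.

:func:`simulate_dataset` emulates the shape of a leave-one-out benchmark
for database incompleteness: a random species-level taxonomy, reads with
known source species, per-gene alignments to the true species plus
weaker partial alignments to sister species and rare off-target hits,
optional two-source chimeric reads, and suppression of all alignments to
a chosen set of taxa ("left-out" references).  Alignments are simulated
directly — no read sequences or base-level error models are involved, so
the generator probes the binning algorithms, not the aligner.

Bit scores are modeled as proportional to the aligned length (2 bits per
codon) plus Gaussian noise, which preserves the property real aligners
have that partial homologous alignments score proportionally lower.
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import (
    MappingTable,
    ReadAlignment,
    ReadRecord,
    write_class_mapping,
    write_tabular,
    write_taxon_mapping,
)
from .errors import ConfigurationError
from .taxonomy import TaxonNode, TaxonomyTree, write_taxonomy_tsv

#: Taxon ids of the worked-example fixture, by name.
FIG1_TAXA = {
    "root": 1,
    "R": 2,
    "P": 3,
    "Q": 4,
    "A": 11, "B": 12, "C": 13, "D": 14,
    "E": 21, "F": 22, "G": 23, "H": 24,
}

#: Alignment intervals of the fixture read (read length 120, all +, 100 bits).
FIG1_INTERVALS = {
    "A": (0, 80),
    "B": (30, 100),
    "C": (10, 70),
    "D": (40, 90),
    "E": (50, 90),
    "F": (45, 80),
    "G": (55, 85),
    "H": (50, 70),
}


def make_fig1_taxonomy() -> TaxonomyTree:
    t = FIG1_TAXA
    nodes = [
        TaxonNode(t["root"], t["root"], "no rank", "root"),
        TaxonNode(t["R"], t["root"], "family", "R"),
        TaxonNode(t["P"], t["R"], "genus", "P"),
        TaxonNode(t["Q"], t["R"], "genus", "Q"),
    ]
    for species in "ABCD":
        nodes.append(TaxonNode(t[species], t["P"], "species", species))
    for species in "EFGH":
        nodes.append(TaxonNode(t[species], t["Q"], "species", species))
    return TaxonomyTree(nodes)


def make_fig1_fixture(
    a_interval: tuple[int, int] | None = None,
) -> tuple[TaxonomyTree, ReadRecord, MappingTable]:
    """The worked-example taxonomy, read record and accession mapping.

    The read (length 120) carries one 100-bit forward-strand alignment
    per species; the union of all intervals is [0, 100).  Per-species
    coverage of that portion: A 80%, B 70%, C 60%, D 50%, E 40%, F 35%,
    G 30%, H 20%; genus P and family R each cover 100%, genus Q 45%.
    With default parameters the read is assigned to species A; passing
    ``a_interval=(0, 60)`` shrinks A's alignment so the read moves up to
    genus P.
    """
    intervals = dict(FIG1_INTERVALS)
    if a_interval is not None:
        intervals["A"] = a_interval
    alignments = []
    taxon_map: dict[str, int] = {}
    for species, (lo, hi) in intervals.items():
        accession = f"prot_{species}"
        taxon_map[accession] = FIG1_TAXA[species]
        alignments.append(
            ReadAlignment(
                read_id="r",
                read_length=120,
                start=lo,
                end=hi,
                strand="+",
                bit_score=100.0,
                ref_accession=accession,
                taxon_id=FIG1_TAXA[species],
            )
        )
    record = ReadRecord("r", 120, alignments)
    return make_fig1_taxonomy(), record, MappingTable(taxon_map=taxon_map)


# -- random datasets -----------------------------------------------------

BITS_PER_BASE = 2.0 / 3.0  # ~2 bits per aligned codon


@dataclass
class SimulationParams:
    """Knobs of the random dataset generator.

    Defaults describe a small but realistic benchmark: a dozen species in
    genera of 2-4, one hundred reads of 5-20 kb spanning 3-8 genes each,
    sister-species alignments over 60-85% of each gene, a couple of bits
    of score noise and a 5% off-target alignment rate.  ``leave_out``
    suppresses every alignment to the listed taxa while keeping their
    reads, emulating an incomplete reference database.
    """

    seed: int = 0
    n_species: int = 12
    species_per_genus: tuple[int, int] = (2, 4)
    n_reads: int = 100
    read_length: tuple[int, int] = (5000, 20000)
    genes_per_read: tuple[int, int] = (3, 8)
    score_noise_sd: float = 2.0
    offtarget_rate: float = 0.05
    chimera_rate: float = 0.0
    sister_rate: float = 0.7
    sister_span: tuple[float, float] = (0.6, 0.85)
    n_gene_families: int = 30
    leave_out: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for name in ("offtarget_rate", "chimera_rate", "sister_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be a probability, got {p}")
        for name in ("species_per_genus", "read_length", "genes_per_read"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigurationError(f"{name} range ({lo}, {hi}) is empty or invalid")


@dataclass
class SimulatedDataset:
    """A generated benchmark with its ground truth.

    ``truth`` maps each read to its source species; chimeric reads are
    mapped to the LCA of their two sources (their leaf sources are kept
    in ``chimera_sources``), a reporting convention for reads that have
    no single correct species.
    """

    tree: TaxonomyTree
    records: list[ReadRecord]
    truth: dict[str, int]
    mapping: MappingTable
    chimera_sources: dict[str, tuple[int, int]] = field(default_factory=dict)


def _build_taxonomy(params: SimulationParams, rng: np.random.Generator) -> TaxonomyTree:
    nodes = [
        TaxonNode(1, 1, "no rank", "root"),
        TaxonNode(2, 1, "family", "family1"),
    ]
    species_ids: list[int] = []
    genus_id = 10
    species_id = 100
    remaining = params.n_species
    while remaining > 0:
        lo, hi = params.species_per_genus
        size = min(int(rng.integers(lo, hi + 1)), remaining)
        nodes.append(TaxonNode(genus_id, 2, "genus", f"genus{genus_id}"))
        for _ in range(size):
            nodes.append(TaxonNode(species_id, genus_id, "species", f"species{species_id}"))
            species_ids.append(species_id)
            species_id += 1
        genus_id += 1
        remaining -= size
    return TaxonomyTree(nodes)


def _gene_boundaries(
    length: int, n_genes: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    cuts = sorted(rng.choice(np.arange(1, length), size=n_genes - 1, replace=False)) if n_genes > 1 else []
    bounds = [0, *map(int, cuts), length]
    return list(zip(bounds, bounds[1:]))


def simulate_dataset(params: SimulationParams | None = None) -> SimulatedDataset:
    """Generate a random benchmark dataset with known per-read truth.

    For each read a true source species is drawn and the read is tiled
    with gene intervals.  Every gene yields a full-length alignment to
    the true species; sister species in the same genus receive, with
    probability ``sister_rate``, a partial alignment over a random
    sub-span of the gene with a proportionally lower score; off-target
    alignments to random species outside the genus appear at
    ``offtarget_rate``.  With probability ``chimera_rate`` a read is a
    two-source chimera split at its midpoint gene boundary.  Taxa in
    ``leave_out`` contribute no alignments at all.
    """
    if params is None:
        params = SimulationParams()
    rng = np.random.default_rng(params.seed)
    tree = _build_taxonomy(params, rng)
    species = sorted(tree.leaves())
    for tid in params.leave_out:
        if tid not in tree:
            raise ConfigurationError(f"leave_out contains unknown taxon id {tid}")

    taxon_map: dict[str, int] = {}
    class_map: dict[str, dict[str, set[str]]] = {"OG": {}}

    def accession(taxon: int, family: int) -> str:
        acc = f"prot{taxon}_F{family}"
        taxon_map[acc] = taxon
        class_map["OG"].setdefault(acc, set()).add(f"OG{family:04d}")
        return acc

    records: list[ReadRecord] = []
    truth: dict[str, int] = {}
    chimera_sources: dict[str, tuple[int, int]] = {}

    for i in range(params.n_reads):
        read_id = f"read{i:04d}"
        length = int(rng.integers(params.read_length[0], params.read_length[1] + 1))
        n_genes = int(rng.integers(params.genes_per_read[0], params.genes_per_read[1] + 1))
        genes = _gene_boundaries(length, n_genes, rng)

        is_chimera = rng.random() < params.chimera_rate and len(species) >= 2
        if is_chimera:
            # a 50/50 chimera: the two sources join at the read midpoint,
            # with genes tiled within each half
            s1, s2 = (int(s) for s in rng.choice(species, size=2, replace=False))
            mid = length // 2
            n1 = max(1, n_genes // 2)
            n2 = max(1, n_genes - n1)
            left = _gene_boundaries(mid, n1, rng)
            right = [(mid + lo, mid + hi) for lo, hi in _gene_boundaries(length - mid, n2, rng)]
            genes = left + right
            sources = [s1] * len(left) + [s2] * len(right)
            truth[read_id] = tree.lca({s1, s2})
            chimera_sources[read_id] = (s1, s2)
        else:
            source = int(rng.choice(species))
            sources = [source] * len(genes)
            truth[read_id] = source

        alignments: list[ReadAlignment] = []

        def add_alignment(taxon: int, lo: int, hi: int, family: int, scale: float = 1.0) -> None:
            # randomness is drawn unconditionally so that the stream (and
            # hence the rest of the dataset) is identical with and without
            # leave_out — a left-out reference changes nothing else
            noise = rng.normal(0.0, params.score_noise_sd) if params.score_noise_sd else 0.0
            strand = "+" if rng.random() < 0.5 else "-"
            if taxon in params.leave_out or hi - lo < 2:
                return
            bits = BITS_PER_BASE * (hi - lo) * scale + noise
            alignments.append(
                ReadAlignment(
                    read_id=read_id,
                    read_length=length,
                    start=lo,
                    end=hi,
                    strand=strand,
                    bit_score=max(bits, 1.0),
                    ref_accession=accession(taxon, family),
                )
            )

        for (lo, hi), source in zip(genes, sources):
            family = int(rng.integers(0, params.n_gene_families))
            add_alignment(source, lo, hi, family)
            if hi - lo < 4:
                continue  # too short to carry meaningful partial alignments
            # partial homologous alignments in sister species
            genus = tree.parent(source)
            for sister in tree.children(genus):
                if sister == source or rng.random() >= params.sister_rate:
                    continue
                frac = rng.uniform(*params.sister_span)
                span = max(2, int(frac * (hi - lo)))
                offset = int(rng.integers(0, hi - lo - span + 1))
                # score tracks the shorter aligned span with a small penalty
                add_alignment(sister, lo + offset, lo + offset + span, family, scale=0.95)
            if rng.random() < params.offtarget_rate:
                others = [s for s in species if tree.parent(s) != genus]
                if others:
                    wrong = int(rng.choice(others))
                    frac = rng.uniform(0.2, 0.5)
                    span = max(2, int(frac * (hi - lo)))
                    offset = int(rng.integers(0, hi - lo - span + 1))
                    add_alignment(wrong, lo + offset, lo + offset + span,
                                  int(rng.integers(0, params.n_gene_families)), scale=0.8)

        records.append(ReadRecord(read_id, length, alignments))

    mapping = MappingTable(
        taxon_map=taxon_map,
        class_maps={ns: {a: frozenset(c) for a, c in amap.items()}
                    for ns, amap in class_map.items()},
    )
    return SimulatedDataset(tree, records, truth, mapping, chimera_sources)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset through the package's file interfaces.

    Emits the TSV taxonomy, the tabular alignment dialect, the two
    mapping TSVs and the truth table; returns the paths.  Output is
    byte-identical for identical datasets.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxonomy": outdir / "taxonomy.tsv",
        "alignments": outdir / "alignments.tsv",
        "taxon_map": outdir / "taxon_map.tsv",
        "class_map": outdir / "class_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["taxonomy"], "w") as fh:
        write_taxonomy_tsv(dataset.tree, fh)
    with open(paths["alignments"], "w") as fh:
        write_tabular((a for r in dataset.records for a in r.alignments), fh)
    with open(paths["taxon_map"], "w") as fh:
        write_taxon_mapping(dataset.mapping.taxon_map, fh)
    with open(paths["class_map"], "w") as fh:
        write_class_mapping(dataset.mapping.class_maps, fh)
    with open(paths["truth"], "w") as fh:
        fh.write("read_id\ttaxon_id\n")
        for read_id, taxon in dataset.truth.items():
            fh.write(f"{read_id}\t{taxon}\n")
    return paths


def write_fig1_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the worked-example fixture through the file interfaces."""
    tree, record, mapping = make_fig1_fixture()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxonomy": outdir / "taxonomy.tsv",
        "alignments": outdir / "alignments.tsv",
        "taxon_map": outdir / "taxon_map.tsv",
    }
    with open(paths["taxonomy"], "w") as fh:
        write_taxonomy_tsv(tree, fh)
    with open(paths["alignments"], "w") as fh:
        write_tabular(record.alignments, fh)
    with open(paths["taxon_map"], "w") as fh:
        write_taxon_mapping(mapping.taxon_map, fh)
    return paths
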