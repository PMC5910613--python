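"""Shared fixtures and random-instance generators for the test suite."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from lrbin.alignment_io import ReadAlignment, ReadRecord
from lrbin.simulate import make_fig1_fixture
from lrbin.taxonomy import TaxonNode, TaxonomyTree


@pytest.fixture
def fig1():
    """The worked-example taxonomy, read record and mapping."""
    return make_fig1_fixture()


@pytest.fixture
def three_node_tree():
    """Root (1) with two leaf children (2, 3)."""
    return TaxonomyTree(
        [
            TaxonNode(1, 1, "no rank", "root"),
            TaxonNode(2, 1, "genus", "P"),
            TaxonNode(3, 1, "genus", "Q"),
        ]
    )


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """A random rooted tree with ids 1..n_nodes (1 is the root)."""
    nodes = [TaxonNode(1, 1, "no rank", "root")]
    for tid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, tid))
        nodes.append(TaxonNode(tid, parent, "clade", f"n{tid}"))
    return TaxonomyTree(nodes)


def random_three_level_tree(rng: np.random.Generator) -> TaxonomyTree:
    """Root -> 2-4 genera -> 2-4 species each; species are the leaves."""
    nodes = [TaxonNode(1, 1, "no rank", "root")]
    species = []
    tid = 2
    for _ in range(int(rng.integers(2, 5))):
        genus = tid
        nodes.append(TaxonNode(genus, 1, "genus", f"g{genus}"))
        tid += 1
        for _ in range(int(rng.integers(2, 5))):
            nodes.append(TaxonNode(tid, genus, "species", f"s{tid}"))
            species.append(tid)
            tid += 1
    return TaxonomyTree(nodes)


def random_record(
    rng: np.random.Generator,
    taxa: list[int],
    read_length: int = 200,
    max_alignments: int = 12,
    read_id: str = "r",
) -> ReadRecord:
    """A read with random integer-coordinate alignments to random taxa."""
    n = int(rng.integers(1, max_alignments + 1))
    alignments = []
    for i in range(n):
        start = int(rng.integers(0, read_length - 1))
        end = int(rng.integers(start + 1, read_length + 1))
        alignments.append(
            ReadAlignment(
                read_id=read_id,
                read_length=read_length,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                bit_score=float(rng.integers(10, 200)),
                ref_accession=f"acc{i}",
                taxon_id=int(rng.choice(taxa)),
            )
        )
    return ReadRecord(read_id, read_length, alignments)
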