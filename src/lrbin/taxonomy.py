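"""Rooted taxonomy loading and queries.

Two on-disk dialects are supported: the NCBI taxonomy dump pair
(``nodes.dmp``/``names.dmp``, fields separated by ``\\t|\\t``) and a simple
4-column TSV (``taxon_id  parent_id  rank  name``).  Only the minimal
subset of the NCBI dump is read: tax_id, parent and rank from nodes.dmp,
and "scientific name" rows from names.dmp.

The tree is rank-agnostic: ranks are carried as labels for reporting only,
and every algorithm in the package works purely on the parent structure.
A node whose parent id equals its own id is the root (NCBI convention).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

from .errors import MalformedTaxonomyError, TaxonNotFoundError


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy."""

    taxon_id: int
    parent_id: int
    rank: str = ""
    name: str = ""


class TaxonomyTree:
    """A rooted taxonomy with parent links, LCA and ancestry queries.

    Construction validates the structural invariants: unique ids, a single
    root (``parent_id == taxon_id``), no dangling parents and no cycles.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise MalformedTaxonomyError(f"duplicate taxon id: {node.taxon_id}")
            self._nodes[node.taxon_id] = node
        if not self._nodes:
            raise MalformedTaxonomyError("taxonomy has no nodes")

        roots = [n.taxon_id for n in self._nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise MalformedTaxonomyError(
                f"expected exactly one root (parent == self), found {len(roots)}"
            )
        self._root_id = roots[0]

        self._children: dict[int, list[int]] = {tid: [] for tid in self._nodes}
        for node in self._nodes.values():
            if node.parent_id not in self._nodes:
                raise MalformedTaxonomyError(
                    f"node {node.taxon_id} has dangling parent id {node.parent_id}"
                )
            if node.taxon_id != self._root_id:
                self._children[node.parent_id].append(node.taxon_id)

        # depth check doubles as cycle detection: every node must reach the root
        self._depth: dict[int, int] = {self._root_id: 0}
        for tid in self._nodes:
            self._depth_of(tid)

    def _depth_of(self, tid: int) -> int:
        path = []
        cur = tid
        while cur not in self._depth:
            path.append(cur)
            cur = self._nodes[cur].parent_id
            if cur in path:
                raise MalformedTaxonomyError(f"cycle detected at taxon id {cur}")
        d = self._depth[cur]
        for node in reversed(path):
            d += 1
            self._depth[node] = d
        return self._depth[tid]

    # -- basic queries ---------------------------------------------------

    @property
    def root_id(self) -> int:
        return self._root_id

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self._nodes

    def __iter__(self) -> Iterator[int]:
        return iter(self._nodes)

    def node(self, taxon_id: int) -> TaxonNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise TaxonNotFoundError(taxon_id) from None

    def parent(self, taxon_id: int) -> int:
        return self.node(taxon_id).parent_id

    def children(self, taxon_id: int) -> list[int]:
        if taxon_id not in self._nodes:
            raise TaxonNotFoundError(taxon_id)
        return list(self._children[taxon_id])

    def is_leaf(self, taxon_id: int) -> bool:
        if taxon_id not in self._nodes:
            raise TaxonNotFoundError(taxon_id)
        return not self._children[taxon_id]

    def leaves(self) -> list[int]:
        return [tid for tid in self._nodes if not self._children[tid]]

    def depth(self, taxon_id: int) -> int:
        if taxon_id not in self._nodes:
            raise TaxonNotFoundError(taxon_id)
        return self._depth[taxon_id]

    def root_path(self, taxon_id: int) -> list[int]:
        """Path from the root down to ``taxon_id``, inclusive."""
        if taxon_id not in self._nodes:
            raise TaxonNotFoundError(taxon_id)
        path = [taxon_id]
        while path[-1] != self._root_id:
            path.append(self._nodes[path[-1]].parent_id)
        path.reverse()
        return path

    def post_order(self) -> Iterator[int]:
        """Iterate taxon ids so that every node follows all its descendants."""
        stack: list[tuple[int, bool]] = [(self._root_id, False)]
        while stack:
            tid, expanded = stack.pop()
            if expanded:
                yield tid
            else:
                stack.append((tid, True))
                for child in self._children[tid]:
                    stack.append((child, False))

    # -- ancestry / LCA --------------------------------------------------

    def is_ancestor_or_equal(self, anc: int, desc: int) -> bool:
        """True iff ``anc`` lies on the root path of ``desc`` (inclusive)."""
        if anc not in self._nodes:
            raise TaxonNotFoundError(anc)
        if desc not in self._nodes:
            raise TaxonNotFoundError(desc)
        while self._depth[desc] > self._depth[anc]:
            desc = self._nodes[desc].parent_id
        return desc == anc

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of taxon ids."""
        ids = list(taxa)
        if not ids:
            raise ValueError("lca requires a non-empty set of taxa")
        for tid in ids:
            if tid not in self._nodes:
                raise TaxonNotFoundError(tid)
        cur = ids[0]
        for tid in ids[1:]:
            cur = self._lca_pair(cur, tid)
            if cur == self._root_id:
                break
        return cur

    def _lca_pair(self, a: int, b: int) -> int:
        while self._depth[a] > self._depth[b]:
            a = self._nodes[a].parent_id
        while self._depth[b] > self._depth[a]:
            b = self._nodes[b].parent_id
        while a != b:
            a = self._nodes[a].parent_id
            b = self._nodes[b].parent_id
        return a

    def child_on_path(self, anc: int, desc: int) -> int:
        """The unique child of ``anc`` lying on the path down to ``desc``.

        ``desc`` must be a strict descendant of ``anc``.
        """
        if not self.is_ancestor_or_equal(anc, desc) or anc == desc:
            raise ValueError(f"{desc} is not a strict descendant of {anc}")
        cur = desc
        while self._nodes[cur].parent_id != anc:
            cur = self._nodes[cur].parent_id
        return cur


# -- parsing ------------------------------------------------------------


def _split_dmp(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def parse_taxonomy(
    nodes_source: TextIO | str,
    names_source: TextIO | str | None = None,
    dialect: str = "tsv",
) -> TaxonomyTree:
    """Load a taxonomy from a text stream (or string).

    Parameters
    ----------
    nodes_source:
        ``nodes.dmp`` content for the ``ncbi_dmp`` dialect, or 4-column TSV
        (taxon_id, parent_id, rank, name) for the ``tsv`` dialect.  A TSV
        header line is detected by a non-numeric first field and skipped.
    names_source:
        Optional ``names.dmp`` content; only "scientific name" rows are
        used, and they override names given in the nodes source.
    dialect:
        ``"tsv"`` or ``"ncbi_dmp"``.
    """
    if isinstance(nodes_source, str):
        nodes_source = io.StringIO(nodes_source)
    if isinstance(names_source, str):
        names_source = io.StringIO(names_source)

    names: dict[int, str] = {}
    if names_source is not None:
        for line in names_source:
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) >= 4 and fields[3].strip() == "scientific name":
                names[int(fields[0])] = fields[1].strip()

    nodes: list[TaxonNode] = []
    if dialect == "ncbi_dmp":
        for line in nodes_source:
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) < 3:
                raise MalformedTaxonomyError(f"bad nodes.dmp line: {line!r}")
            tid = int(fields[0])
            nodes.append(
                TaxonNode(
                    taxon_id=tid,
                    parent_id=int(fields[1]),
                    rank=fields[2].strip(),
                    name=names.get(tid, ""),
                )
            )
    elif dialect == "tsv":
        for lineno, line in enumerate(nodes_source, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and not fields[0].strip().isdigit():
                continue  # header
            if len(fields) < 2:
                raise MalformedTaxonomyError(
                    f"line {lineno}: expected >= 2 tab-separated fields"
                )
            try:
                tid = int(fields[0])
                pid = int(fields[1])
            except ValueError as exc:
                raise MalformedTaxonomyError(f"line {lineno}: {exc}") from None
            rank = fields[2].strip() if len(fields) > 2 else ""
            name = fields[3].strip() if len(fields) > 3 else ""
            nodes.append(
                TaxonNode(taxon_id=tid, parent_id=pid, rank=rank, name=names.get(tid, name))
            )
    else:
        raise ValueError(f"unknown taxonomy dialect: {dialect!r}")

    if not nodes:
        raise MalformedTaxonomyError("taxonomy source is empty")
    return TaxonomyTree(nodes)


def write_taxonomy_tsv(tree: TaxonomyTree, stream: TextIO) -> None:
    """Write the 4-column TSV dialect (with header) for a tree."""
    stream.write("taxon_id\tparent_id\trank\tname\n")
    for tid in sorted(tree):
        node = tree.node(tid)
        stream.write(f"{node.taxon_id}\t{node.parent_id}\t{node.rank}\t{node.name}\n")
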