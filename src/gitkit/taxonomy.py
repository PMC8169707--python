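"""Rank-labelled taxonomy tree: lineage, rank projection, lowest common ancestor.

The tree is a parent-pointer structure in the spirit of the NCBI taxonomy
dumps (``nodes.dmp`` / ``names.dmp``, pipe-and-tab delimited).  It backs the
two taxonomic-assignment strategies used during annotation (best hit and LCA
over retained homology hits) and the rank projections used in comparisons
(e.g. tallying assigned taxa at the order rank).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

from .errors import ArgumentError, StructureError, UnknownTaxonError

#: Taxon id reserved for "unassigned".
UNASSIGNED = 0


@dataclass
class TaxNode:
    taxon_id: int
    parent_id: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """Parent-pointer taxonomy with exactly one self-parented root."""

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[int, TaxNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise StructureError(f"duplicate taxon id {node.taxon_id}")
            self.nodes[node.taxon_id] = node
        roots = [n.taxon_id for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one self-parented root, found {len(roots)}")
        self.root = roots[0]
        self._validate()
        self._depth: dict[int, int] = {}

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.parent_id not in self.nodes:
                raise StructureError(
                    f"taxon {node.taxon_id} references missing parent {node.parent_id}"
                )
        # Every lineage must terminate at the root (no cycles).
        state: dict[int, int] = {}  # 0 = in progress, 1 = reaches root
        for start in self.nodes:
            path = []
            current = start
            while True:
                if state.get(current) == 1:
                    break
                if current in path or state.get(current) == 0:
                    raise StructureError(f"cycle detected through taxon {current}")
                path.append(current)
                state[current] = 0
                if current == self.root:
                    break
                current = self.nodes[current].parent_id
            for taxon in path:
                state[taxon] = 1

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def _require(self, taxon_id: int) -> TaxNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise UnknownTaxonError(f"unknown taxon id {taxon_id}") from None

    def parent(self, taxon_id: int) -> int:
        return self._require(taxon_id).parent_id

    def rank(self, taxon_id: int) -> str:
        return self._require(taxon_id).rank

    def name(self, taxon_id: int) -> str:
        return self._require(taxon_id).name

    def lineage(self, taxon_id: int) -> list[int]:
        """Root-to-taxon path of taxon ids."""
        self._require(taxon_id)
        path = []
        current = taxon_id
        while current != self.root:
            path.append(current)
            current = self.nodes[current].parent_id
        path.append(self.root)
        path.reverse()
        return path

    def depth(self, taxon_id: int) -> int:
        if taxon_id not in self._depth:
            self._depth[taxon_id] = len(self.lineage(taxon_id)) - 1
        return self._depth[taxon_id]

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor of a set of taxa.

        Unassigned members (taxon 0) are dropped first so that missing
        evidence does not force the result to the root; an all-unassigned
        set returns 0.
        """
        taxa = set(taxa)
        if not taxa:
            raise ArgumentError("lca of an empty taxon set")
        taxa.discard(UNASSIGNED)
        if not taxa:
            return UNASSIGNED
        common: set[int] | None = None
        for taxon in taxa:
            ancestors = set(self.lineage(taxon))
            common = ancestors if common is None else common & ancestors
        assert common  # root is ancestral to everything
        return max(common, key=self.depth)

    def project_rank(self, taxon_id: int, rank: str) -> int | None:
        """Deepest ancestor-or-self whose rank matches (case-insensitive)."""
        wanted = rank.lower()
        for candidate in reversed(self.lineage(taxon_id)):
            if self.nodes[candidate].rank.lower() == wanted:
                return candidate
        return None


def _dump_fields(line: str) -> list[str]:
    # nodes.dmp/names.dmp rows are "<f>\t|\t<f>\t|\t...\t|" (or bare pipes).
    return [field.strip("\t ") for field in line.rstrip("\n").rstrip("|\t ").split("|")]


def load_taxonomy(nodes_source: TextIO | Iterable[str],
                  names_source: TextIO | Iterable[str] | None = None) -> TaxonomyTree:
    """Load a tree from nodes/names dump streams.

    Only scientific names are taken from the names stream; when a names row
    carries no name-class field its name is accepted as-is.
    """
    nodes = []
    for line in nodes_source:
        if not line.strip():
            continue
        fields = _dump_fields(line)
        if len(fields) < 3:
            raise StructureError(f"nodes dump row has fewer than 3 fields: {line!r}")
        nodes.append(TaxNode(int(fields[0]), int(fields[1]), fields[2]))
    tree = TaxonomyTree(nodes)
    if names_source is not None:
        for line in names_source:
            if not line.strip():
                continue
            fields = _dump_fields(line)
            taxon_id = int(fields[0])
            name_class = fields[3] if len(fields) > 3 else "scientific name"
            if name_class == "scientific name" and taxon_id in tree.nodes:
                tree.nodes[taxon_id].name = fields[1]
    return tree


def load_taxonomy_files(nodes_path, names_path=None) -> TaxonomyTree:
    with open(nodes_path, encoding="utf-8") as nodes_handle:
        if names_path is None:
            return load_taxonomy(nodes_handle)
        with open(names_path, encoding="utf-8") as names_handle:
            return load_taxonomy(nodes_handle, names_handle)


def dump_taxonomy(tree: TaxonomyTree) -> tuple[str, str]:
    """Serialize a tree back to (nodes.dmp text, names.dmp text)."""
    nodes_lines = []
    names_lines = []
    for taxon_id in sorted(tree.nodes):
        node = tree.nodes[taxon_id]
        nodes_lines.append(f"{node.taxon_id}\t|\t{node.parent_id}\t|\t{node.rank}\t|")
        names_lines.append(f"{node.taxon_id}\t|\t{node.name}\t|\t\t|\tscientific name\t|")
    return "\n".join(nodes_lines) + "\n", "\n".join(names_lines) + "\n"
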