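"""Taxonomy tree loading, lineages, and fixed-depth slim projection.

The tree is read from NCBI taxdump-dialect ``nodes.dmp``/``names.dmp``
files (pipe-delimited, ``\\t|\\t`` separators).  Depth is counted in parent
hops from the root: root = 0, its children = 1, and so on.  A *tax slim* at
depth *d* is the reduced view of the tree in which every node deeper than
*d* is reported through its ancestor at exactly depth *d*; nodes at depth
<= *d* pass through unchanged.

Subjects of the reference collection are resolved to tax ids through a
local two-column mapping table (accession2taxid dialect: subject id, TAB,
taxid).  A subject absent from the table resolves to the :data:`UNMAPPED`
sentinel, which the census stage tallies under its "unresolved" category —
it is a value, never an error.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Union

__all__ = [
    "UNMAPPED",
    "TaxNode",
    "TaxonomyTree",
    "SubjectTaxMap",
    "TaxonomyError",
    "load_taxonomy",
    "load_subject_map",
    "lineage",
    "slim_project",
    "resolve_subject",
]

#: Sentinel taxid for subjects absent from the subject→taxid map.
UNMAPPED = -1


class TaxonomyError(ValueError):
    """Structural problem in the taxonomy: orphans, cycles, missing root."""


@dataclass
class TaxNode:
    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str = ""
    depth: int = -1  # parent hops from root; filled at load time


@dataclass
class TaxonomyTree:
    nodes: Dict[int, TaxNode]
    root_taxid: int

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, taxid: int) -> str:
        node = self.nodes.get(taxid)
        return node.scientific_name if node is not None else ""


@dataclass
class SubjectTaxMap:
    """subject_id → taxid mapping (accession2taxid dialect)."""

    mapping: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self.mapping


def _taxdump_fields(line: str) -> List[str]:
    return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]


def load_taxonomy(
    nodes_path: Union[str, Path],
    names_path: Union[str, Path],
) -> TaxonomyTree:
    """Load a taxdump-dialect tree and compute depths by traversal from root.

    The root is the node that is its own parent.  Orphan parents and cycles
    (nodes unreachable from the root) raise :class:`TaxonomyError` listing
    the offending tax ids.
    """
    nodes: Dict[int, TaxNode] = {}
    with open(nodes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _taxdump_fields(line)
            if len(fields) < 3:
                raise TaxonomyError(f"malformed nodes line: {line!r}")
            taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            nodes[taxid] = TaxNode(taxid=taxid, parent_taxid=parent, rank=rank)

    with open(names_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _taxdump_fields(line)
            taxid = int(fields[0])
            name_class = fields[3] if len(fields) > 3 else "scientific name"
            if taxid in nodes and name_class == "scientific name":
                nodes[taxid].scientific_name = fields[1]

    roots = [t for t, n in nodes.items() if n.parent_taxid == t]
    if not nodes:
        raise TaxonomyError("empty taxonomy")
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one root (self-parented node), found {roots}")
    root = roots[0]

    orphans = sorted(
        t for t, n in nodes.items() if n.parent_taxid not in nodes
    )
    if orphans:
        raise TaxonomyError(f"orphan nodes (parent absent): {orphans}")

    children: Dict[int, List[int]] = {t: [] for t in nodes}
    for t, n in nodes.items():
        if t != root:
            children[n.parent_taxid].append(t)

    nodes[root].depth = 0
    queue = deque([root])
    seen = 1
    while queue:
        current = queue.popleft()
        for child in children[current]:
            nodes[child].depth = nodes[current].depth + 1
            seen += 1
            queue.append(child)
    if seen != len(nodes):
        unreachable = sorted(t for t, n in nodes.items() if n.depth < 0)
        raise TaxonomyError(f"cycle or disconnected component involving: {unreachable}")

    return TaxonomyTree(nodes=nodes, root_taxid=root)


def lineage(tree: TaxonomyTree, taxid: int) -> List[int]:
    """Root-to-node path of tax ids; consecutive entries are parent→child."""
    if taxid not in tree.nodes:
        raise KeyError(f"taxid {taxid} not in taxonomy")
    path = []
    current = taxid
    while True:
        path.append(current)
        parent = tree.nodes[current].parent_taxid
        if parent == current:
            break
        current = parent
    path.reverse()
    return path


def slim_project(tree: TaxonomyTree, taxid: int, depth: int) -> int:
    """Project *taxid* onto the tax slim at *depth*.

    Returns the ancestor at exactly *depth* for deeper nodes; nodes at depth
    <= *depth* pass through unchanged.  Idempotent, and the result always
    lies on ``lineage(tree, taxid)``.
    """
    if depth < 0:
        raise ValueError(f"slim depth must be >= 0, got {depth}")
    node = tree.nodes.get(taxid)
    if node is None:
        raise KeyError(f"taxid {taxid} not in taxonomy")
    if node.depth <= depth:
        return taxid
    current = taxid
    for _ in range(node.depth - depth):
        current = tree.nodes[current].parent_taxid
    return current


def load_subject_map(
    path: Union[str, Path],
    tree: TaxonomyTree | None = None,
) -> SubjectTaxMap:
    """Load a two-column (subject_id TAB taxid) table.

    When *tree* is given, every mapped taxid must exist in it — merged or
    deleted ids are not patched up, they are load errors.
    """
    mapping: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed subject-map line: {line!r}")
            mapping[parts[0]] = int(parts[1])
    if tree is not None:
        missing = sorted({t for t in mapping.values() if t not in tree.nodes})
        if missing:
            raise TaxonomyError(f"subject map references unknown taxids: {missing}")
    return SubjectTaxMap(mapping=mapping)


def resolve_subject(subject_map: SubjectTaxMap, subject_id: str) -> int:
    """Taxid for a subject, or :data:`UNMAPPED` if the table lacks it."""
    return subject_map.mapping.get(subject_id, UNMAPPED)
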