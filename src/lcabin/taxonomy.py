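"""In-memory taxonomy model with LCA and rank queries.

The taxonomy is a rooted tree of named, ranked nodes in the style of the
NCBI taxonomy: every node carries an integer id, a parent id (the root
points to itself, as node 1 does in the NCBI dumps), a rank drawn from a
fixed ordered vocabulary, and a name.  Two input dialects are accepted:
the NCBI ``nodes.dmp``/``names.dmp`` pipe-delimited format and a plain
4-column TSV (id, parent, rank, name).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

__all__ = [
    "RANKS",
    "TaxNode",
    "Taxonomy",
    "TaxonomyError",
    "load_taxonomy",
]

#: Ordered rank vocabulary, shallow to deep.  ``norank`` is transparent to
#: rank queries; unknown rank strings are coerced to it.
RANKS: tuple[str, ...] = (
    "root",
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

NO_RANK = "norank"


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy source (cycle, orphan, duplicate)."""


@dataclass(frozen=True)
class TaxNode:
    taxon_id: int
    parent_id: int
    rank: str
    name: str

    @property
    def is_root(self) -> bool:
        return self.taxon_id == self.parent_id


@dataclass
class Taxonomy:
    """Rooted taxonomic tree supporting LCA and fixed-rank queries."""

    nodes: dict[int, TaxNode] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)
    root_id: int = 0
    _depth: dict[int, int] = field(default_factory=dict, repr=False)

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxon_id: int) -> TaxNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon id {taxon_id}") from None

    def parent(self, taxon_id: int) -> int:
        return self.node(taxon_id).parent_id

    def depth(self, taxon_id: int) -> int:
        """Number of parent hops from *taxon_id* to the root."""
        d = self._depth.get(taxon_id)
        if d is None:
            node = self.node(taxon_id)
            d = 0 if node.is_root else self.depth(node.parent_id) + 1
            self._depth[taxon_id] = d
        return d

    def path_to_root(self, taxon_id: int) -> list[int]:
        """Ids from *taxon_id* (inclusive) up to and including the root."""
        path = [taxon_id]
        node = self.node(taxon_id)
        while not node.is_root:
            node = self.node(node.parent_id)
            path.append(node.taxon_id)
        return path

    def is_ancestor_or_self(self, ancestor: int, descendant: int) -> bool:
        node = self.node(descendant)
        while True:
            if node.taxon_id == ancestor:
                return True
            if node.is_root:
                return False
            node = self.node(node.parent_id)

    def subtree_ids(self, taxon_id: int) -> Iterator[int]:
        """All ids in the subtree rooted at *taxon_id*, preorder."""
        stack = [taxon_id]
        while stack:
            tid = stack.pop()
            yield tid
            stack.extend(reversed(self.children.get(tid, ())))

    def lca(self, ids: Iterable[int]) -> int:
        return lca(self, ids)

    def ancestor_at_rank(self, taxon_id: int, rank: str) -> int | None:
        return ancestor_at_rank(self, taxon_id, rank)

    def validate(self) -> None:
        roots = [n.taxon_id for n in self.nodes.values() if n.is_root]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {roots}")
        for tid in self.nodes:
            seen = set()
            node = self.nodes[tid]
            while not node.is_root:
                if node.taxon_id in seen:
                    raise TaxonomyError(f"cycle detected at taxon {node.taxon_id}")
                seen.add(node.taxon_id)
                parent = self.nodes.get(node.parent_id)
                if parent is None:
                    raise TaxonomyError(
                        f"taxon {node.taxon_id} references unknown parent {node.parent_id}"
                    )
                node = parent


def _normalize_rank(rank: str) -> str:
    rank = rank.strip().lower().replace("superkingdom", "domain")
    return rank if rank in _RANK_INDEX else NO_RANK


def lca(tax: Taxonomy, ids: Iterable[int]) -> int:
    """Lowest common ancestor of a non-empty id set.

    The deepest node that is ancestral-or-equal to every id; ``lca({x}) == x``.
    """
    it = iter(ids)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("lca of an empty id set is undefined") from None
    current = tax.path_to_root(first)  # deepest-first chain
    current_set = set(current)
    for tid in it:
        if tid in current_set:
            # cut the chain at tid: everything below it is no longer common
            while current[0] != tid:
                current_set.discard(current.pop(0))
            continue
        other = set(tax.path_to_root(tid))
        while current and current[0] not in other:
            current_set.discard(current.pop(0))
    return current[0]


def ancestor_at_rank(tax: Taxonomy, taxon_id: int, rank: str) -> int | None:
    """Walk rootward from *taxon_id* (inclusive); first node whose rank
    equals *rank*, or ``None`` if no such ancestor exists."""
    if rank not in _RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    node = tax.node(taxon_id)
    while True:
        if node.rank == rank:
            return node.taxon_id
        if node.is_root:
            return None
        node = tax.node(node.parent_id)


def _split_dmp(line: str) -> list[str]:
    # NCBI dump rows end with "\t|\n" and are "\t|\t"-delimited
    return [f.strip() for f in line.rstrip("\n").rstrip("|\t ").split("\t|\t")]


def _iter_rows(source: TextIO | str) -> Iterator[list[str]]:
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source
    for line in lines:
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t|\t" in line or line.rstrip().endswith("|"):
            yield _split_dmp(line)
        else:
            yield [f.strip() for f in line.rstrip("\n").split("\t")]


def load_taxonomy(nodes_source: TextIO | str, names_source: TextIO | str | None = None) -> Taxonomy:
    """Build a :class:`Taxonomy` from tabular sources.

    ``nodes_source`` rows carry (taxon_id, parent_id, rank[, name]); the
    NCBI ``nodes.dmp`` dialect and a plain TSV are auto-detected by
    delimiter.  ``names_source``, when given, carries (taxon_id, name[,
    unique-name, name-class]); the "scientific name" class wins when a
    taxon has several names.
    """
    nodes: dict[int, TaxNode] = {}
    inline_names: dict[int, str] = {}
    for row in _iter_rows(nodes_source):
        if len(row) < 3:
            raise TaxonomyError(f"nodes row too short: {row!r}")
        tid, pid = int(row[0]), int(row[1])
        if tid in nodes:
            raise TaxonomyError(f"duplicate taxon id {tid}")
        rank = _normalize_rank(row[2])
        nodes[tid] = TaxNode(tid, pid, rank, name=str(tid))
        if len(row) >= 4 and row[3]:
            inline_names[tid] = row[3]

    names: dict[int, str] = dict(inline_names)
    if names_source is not None:
        preferred: dict[int, bool] = {tid: False for tid in names}
        for row in _iter_rows(names_source):
            if len(row) < 2:
                continue
            tid = int(row[0])
            name_class = row[3].lower() if len(row) >= 4 else "scientific name"
            is_scientific = name_class == "scientific name"
            if tid not in names or (is_scientific and not preferred.get(tid, False)):
                names[tid] = row[1]
                preferred[tid] = is_scientific

    tax = Taxonomy()
    for tid, node in nodes.items():
        name = names.get(tid, node.name)
        rank = node.rank
        if node.is_root and rank == NO_RANK:
            rank = "root"
        tax.nodes[tid] = TaxNode(tid, node.parent_id, rank, name)
    for tid, node in tax.nodes.items():
        if node.is_root:
            tax.root_id = tid
        else:
            tax.children.setdefault(node.parent_id, []).append(tid)
    for kids in tax.children.values():
        kids.sort()
    tax.validate()
    return tax
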