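"""Functional classification trees: generic hierarchies and InterPro2GO.

A :class:`ClassificationTree` is a forest of labelled nodes binned
against by node id or by an attached external id (payload).  The
InterPro2GO builder constructs the specific two-tier-GO/InterPro layout:
three Gene Ontology domain roots plus an "Unclassified" catch-all on the
first tier, the GO-slim terms on the second, and InterPro family nodes
below.  A family annotated to exactly one slim term within a domain
hangs under that term; a family annotated to several slim terms of one
domain hangs under that domain's "Other" node; a family with no usable
GO annotation hangs under "Unclassified".  Each family therefore occurs
at most three times, at most once per domain, and the result is a tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from .binning import ReadAssignment, UNASSIGNED

__all__ = [
    "ClassificationTree",
    "InterPro2GOInputs",
    "HierarchyError",
    "GO_DOMAINS",
    "UNCLASSIFIED_ID",
    "build_interpro2go",
    "load_hierarchy",
    "parse_interpro2go_mapping",
    "rollup_counts",
]

#: The three GO domain roots: id -> tier-1 node label.
GO_DOMAINS: dict[str, str] = {
    "GO:0008150": "GO:0008150 biological process",
    "GO:0005575": "GO:0005575 cellular component",
    "GO:0003674": "GO:0003674 molecular function",
}

UNCLASSIFIED_ID = "Unclassified"


class HierarchyError(ValueError):
    pass


@dataclass
class ClassificationTree:
    """Forest of (label, parent, payload external ids) nodes."""

    name: str
    labels: dict[object, str] = field(default_factory=dict)
    parents: dict[object, object] = field(default_factory=dict)  # roots map to None
    payloads: dict[object, set[str]] = field(default_factory=dict)
    roots: list[object] = field(default_factory=list)
    #: external id -> node ids carrying it (a family can be multi-placed)
    placements: dict[str, list[object]] = field(default_factory=dict)
    diagnostics: dict[str, int] = field(default_factory=dict)

    def add_node(self, class_id, label: str, parent=None, payload: Iterable[str] = ()) -> None:
        if class_id in self.labels:
            raise HierarchyError(f"duplicate class id {class_id!r}")
        if parent is not None and parent not in self.labels:
            raise HierarchyError(f"node {class_id!r} references unknown parent {parent!r}")
        self.labels[class_id] = label
        self.parents[class_id] = parent
        if parent is None:
            self.roots.append(class_id)
        payload = set(payload)
        if payload:
            self.payloads[class_id] = payload
            for ext in payload:
                self.placements.setdefault(ext, []).append(class_id)

    def children(self, class_id) -> list[object]:
        return [c for c, p in self.parents.items() if p == class_id]

    def knows(self, class_id) -> bool:
        """Binnable: an internal node id or an attached external id."""
        return class_id in self.labels or class_id in self.placements

    def nodes_for(self, class_id) -> list[object]:
        """Tree node(s) a binnable id refers to (itself, or its placements)."""
        if class_id in self.labels:
            return [class_id]
        return list(self.placements.get(class_id, ()))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[object]:
        return iter(self.labels)


@dataclass
class InterPro2GOInputs:
    """Inputs for the InterPro2GO tree, as distributed by EBI.

    family_to_go: InterPro accession -> GO term ids annotated to it.
    goslim_terms: slim term id -> (label, GO domain id).
    go_ancestry: GO term id -> slim ancestor term ids (a slim term is its
    own ancestor unless the mapping says otherwise).
    all_families: InterPro accession -> label, the full family universe.
    """

    family_to_go: dict[str, set[str]]
    goslim_terms: dict[str, tuple[str, str]]
    go_ancestry: dict[str, set[str]]
    all_families: dict[str, str]


def _slim_ancestors(inp: InterPro2GOInputs, go_term: str) -> set[str]:
    anc = set(inp.go_ancestry.get(go_term, ()))
    if go_term in inp.goslim_terms:
        anc.add(go_term)
    return {t for t in anc if t in inp.goslim_terms}


def build_interpro2go(inp: InterPro2GOInputs) -> ClassificationTree:
    """Construct the InterPro2GO classification tree.

    Deterministic: slim terms and family accessions are laid out in
    lexicographic order, "Other" nodes are created lazily with the stable
    id ``<domain_id>:Other``.  Family node ids are ``<parent_id>::<acc>``
    so a multi-placed family yields distinct nodes, each carrying the
    accession as payload.  A GO annotation with no slim ancestor in any
    domain is ignored for placement and counted in the diagnostics.
    """
    tree = ClassificationTree(name="InterPro2GO")
    for domain_id in sorted(GO_DOMAINS):
        tree.add_node(domain_id, GO_DOMAINS[domain_id], parent=None)
    tree.add_node(UNCLASSIFIED_ID, "Unclassified", parent=None)

    for term in sorted(inp.goslim_terms):
        label, domain_id = inp.goslim_terms[term]
        if domain_id not in GO_DOMAINS:
            raise HierarchyError(f"slim term {term} names unknown GO domain {domain_id!r}")
        if term in GO_DOMAINS:
            continue  # the domain roots themselves are already tier 1
        tree.add_node(term, f"{term} {label}", parent=domain_id)

    dropped_terms = 0
    for acc in sorted(inp.all_families):
        label = inp.all_families[acc]
        per_domain: dict[str, set[str]] = {}
        for go in sorted(inp.family_to_go.get(acc, ())):
            slims = _slim_ancestors(inp, go)
            if not slims:
                dropped_terms += 1
                continue
            for slim in slims:
                per_domain.setdefault(inp.goslim_terms[slim][1], set()).add(slim)
        if not per_domain:
            tree.add_node(f"{UNCLASSIFIED_ID}::{acc}", label, UNCLASSIFIED_ID, payload=[acc])
            continue
        for domain_id in sorted(per_domain):
            slims = per_domain[domain_id]
            if len(slims) == 1:
                parent: object = next(iter(slims))
                if parent == domain_id:
                    parent = domain_id
            else:
                parent = f"{domain_id}:Other"
                if parent not in tree.labels:
                    tree.add_node(parent, "Other", domain_id)
            tree.add_node(f"{parent}::{acc}", label, parent, payload=[acc])
    tree.diagnostics["go_terms_without_slim_ancestor"] = dropped_terms
    return tree


ROOT_TOKEN = "ROOT"


def load_hierarchy(source: TextIO | str, name: str = "hierarchy") -> ClassificationTree:
    """Load a generic functional hierarchy from 3-column TSV rows
    (class_id, parent_id or ``ROOT``, label).

    Suited to SEED-like subsystem/role and eggNOG-like COG hierarchies.
    Parents may appear after their children (two-pass resolution); an
    orphan parent or duplicate id is a structural error.  Every node id
    is binnable, inner nodes included.
    """
    lines = source.splitlines() if isinstance(source, str) else list(source)
    rows: list[tuple[str, str, str]] = []
    ids: set[str] = set()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise HierarchyError(f"line {lineno}: expected 3 columns, got {len(fields)}")
        cid, pid, label = fields[0].strip(), fields[1].strip(), fields[2]
        if cid in ids:
            raise HierarchyError(f"line {lineno}: duplicate class id {cid!r}")
        ids.add(cid)
        rows.append((cid, pid, label))

    tree = ClassificationTree(name=name)
    pending = rows
    while pending:
        deferred = []
        progressed = False
        for cid, pid, label in pending:
            if pid == ROOT_TOKEN:
                tree.add_node(cid, label, parent=None)
                progressed = True
            elif pid in tree.labels:
                tree.add_node(cid, label, parent=pid)
                progressed = True
            else:
                deferred.append((cid, pid, label))
        if not progressed:
            missing = sorted({pid for _, pid, _ in deferred})
            raise HierarchyError(f"unresolvable parent id(s): {missing}")
        pending = deferred
    return tree


def rollup_counts(
    tree: ClassificationTree, assignments: Iterable[ReadAssignment]
) -> dict[object, tuple[int, int]]:
    """Per-node (assigned, summarized) counts for a list of assignments.

    ``assigned`` counts direct assignments, ``summarized`` adds every
    descendant's.  An id placed at several tree positions (an InterPro
    family mapping to multiple GO domains) receives its full count at
    every placement, so tier-1 sums can exceed the classified-read total;
    consumers must report this multi-counting.  Unknown ids go to a
    diagnostics tally, not an error.
    """
    assigned: dict[object, int] = {}
    unknown = 0
    for a in assignments:
        if a.class_id == UNASSIGNED:
            continue
        nodes = tree.nodes_for(a.class_id)
        if not nodes:
            unknown += 1
            continue
        for node in nodes:
            assigned[node] = assigned.get(node, 0) + 1

    summarized: dict[object, int] = {cid: assigned.get(cid, 0) for cid in tree.labels}
    # children-before-parents: sort by depth descending
    def depth(cid) -> int:
        d = 0
        while tree.parents[cid] is not None:
            cid = tree.parents[cid]
            d += 1
        return d

    for cid in sorted(tree.labels, key=depth, reverse=True):
        parent = tree.parents[cid]
        if parent is not None:
            summarized[parent] += summarized[cid]

    tree.diagnostics["rollup_unknown_ids"] = unknown
    return {cid: (assigned.get(cid, 0), summarized[cid]) for cid in tree.labels}


def parse_interpro2go_mapping(source: TextIO | str) -> dict[str, set[str]]:
    """Parse the EBI ``interpro2go`` line dialect into family -> GO ids.

    Lines look like ``InterPro:IPR000001 Kringle > GO:kringle domain ;
    GO:0008150``; comment lines start with ``!``.
    """
    mapping: dict[str, set[str]] = {}
    lines = source.splitlines() if isinstance(source, str) else source
    for line in lines:
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        if not line.startswith("InterPro:") or ";" not in line:
            continue
        head, go_id = line.rsplit(";", 1)
        acc = head.split()[0].split(":", 1)[1]
        mapping.setdefault(acc, set()).add(go_id.strip())
    return mapping
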