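"""Read-to-taxon binning: naive LCA, weighted LCA, min-support, projection.

Two binning rules are provided.  The *naive LCA* assigns each read to the
lowest common ancestor of all taxa for which the read has a significant
alignment: reads hitting widely conserved genes land on high-level taxa,
reads hitting clade-specific genes land deep.  The *weighted LCA* is a
two-phase refinement aimed at profiling.  Phase 1 assigns every reference
sequence S a weight: the number of reads that align only to S, or also to
other references that share S's species assignment.  Phase 2 places each
read on the lowest taxonomy node whose subtree holds at least a coverage
fraction (default 75%) of the total weight of the read's references.
Because the coverage threshold exceeds 50%, the qualifying nodes always
form a root-to-node chain and the placement is unique.

Both rules bin across all ranks; :func:`project_to_rank` converts such a
binning into a fixed-rank profile by rolling below-rank counts up and
pushing above-rank counts down proportionally to the read mass observed
on or below each child, with exact integer conservation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .alignment_io import ReadAlignments, RefClassMap, resolve_class
from .taxonomy import Taxonomy, ancestor_at_rank, lca

__all__ = [
    "UNASSIGNED",
    "UNRESOLVED",
    "ReadAssignment",
    "RefWeights",
    "SampleProfile",
    "naive_lca",
    "compute_ref_weights",
    "weighted_lca",
    "min_support_filter",
    "project_to_rank",
    "functional_bin",
    "assignments_to_counts",
]

#: Sentinel class id for reads with no surviving, resolvable alignment.
UNASSIGNED = "UNASSIGNED"
#: Sentinel profile bin for reads that cannot reach the requested rank.
UNRESOLVED = "UNRESOLVED"


@dataclass
class ReadAssignment:
    read_id: str
    class_id: object  # taxon_id | functional class id | UNASSIGNED
    algorithm: str  # {naive-lca, weighted-lca, best-hit}
    score_used: float = 0.0

    @property
    def assigned(self) -> bool:
        return self.class_id != UNASSIGNED


@dataclass
class RefWeights:
    """Phase-1 output of the weighted LCA."""

    weights: dict[str, int] = field(default_factory=dict)
    species_of: dict[str, int] = field(default_factory=dict)


@dataclass
class SampleProfile:
    """class_id -> count profile for one sample, plus provenance."""

    sample_name: str
    classification_name: str
    counts: dict[object, float] = field(default_factory=dict)
    total_reads: int = 0
    parameters: dict[str, object] = field(default_factory=dict)

    @property
    def classified_total(self) -> float:
        return sum(v for k, v in self.counts.items() if k not in (UNASSIGNED, UNRESOLVED))


def _resolve_taxa(ra: ReadAlignments, tax: Taxonomy, ref_map: RefClassMap) -> list[tuple[str, int]]:
    """(ref_id, taxon_id) for every record resolving into the taxonomy."""
    out = []
    for rec in ra.records:
        tid = resolve_class(ref_map, rec.ref_id)
        if tid is not None and tid in tax:
            out.append((rec.ref_id, tid))
    return out


def naive_lca(ra: ReadAlignments, tax: Taxonomy, ref_map: RefClassMap) -> ReadAssignment:
    """Assign one read to the LCA of the taxa its alignments resolve to.

    Unresolvable records (no mapping hit, or a taxon absent from the
    taxonomy) are discarded; a read with no resolvable record is
    UNASSIGNED.  The input must already have passed the significance
    filter.
    """
    resolved = _resolve_taxa(ra, tax, ref_map)
    if not resolved:
        return ReadAssignment(ra.read_id, UNASSIGNED, "naive-lca")
    node = lca(tax, {tid for _, tid in resolved})
    return ReadAssignment(ra.read_id, node, "naive-lca", score_used=ra.records[0].bitscore)


def _species_of(tax: Taxonomy, taxon_id: int) -> int:
    sp = ancestor_at_rank(tax, taxon_id, "species")
    return sp if sp is not None else taxon_id


def compute_ref_weights(
    all_reads: Iterable[ReadAlignments], tax: Taxonomy, ref_map: RefClassMap
) -> RefWeights:
    """Phase 1 of the weighted LCA: one full pass over the sample.

    A read whose resolved references all share one species assignment
    increments the weight of every reference it aligns to; reads whose
    references span two or more species contribute nothing.  Every
    reference seen in a surviving alignment ends with weight >= 1 (a
    floor applied after the pass, so purely ambiguous references remain
    placeable in phase 2).
    """
    rw = RefWeights()
    for ra in all_reads:
        resolved = _resolve_taxa(ra, tax, ref_map)
        if not resolved:
            continue
        species = set()
        for ref_id, tid in resolved:
            sp = rw.species_of.get(ref_id)
            if sp is None:
                sp = _species_of(tax, tid)
                rw.species_of[ref_id] = sp
            rw.weights.setdefault(ref_id, 0)
            species.add(sp)
        if len(species) == 1:
            for ref_id, _ in resolved:
                rw.weights[ref_id] += 1
    for ref_id, w in rw.weights.items():
        if w == 0:
            rw.weights[ref_id] = 1
    return rw


def weighted_lca(
    ra: ReadAlignments,
    ref_weights: RefWeights,
    tax: Taxonomy,
    ref_map: RefClassMap,
    coverage: float = 0.75,
) -> ReadAssignment:
    """Phase 2: place one read at the lowest node covering the weight.

    With W the summed weight of the read's resolved references, the read
    goes to the deepest node whose subtree contains at least
    ``coverage * W`` of that weight.  The root always qualifies, so an
    assignment exists whenever any reference resolves.  *coverage* must
    exceed 0.5 so the qualifying nodes form a single chain.
    """
    if not coverage > 0.5:
        raise ValueError(f"coverage must exceed 0.5 (got {coverage})")
    resolved = _resolve_taxa(ra, tax, ref_map)
    if not resolved:
        return ReadAssignment(ra.read_id, UNASSIGNED, "weighted-lca")
    # attach each reference's weight to its taxon node
    node_weight: dict[int, int] = {}
    total = 0
    for ref_id, tid in resolved:
        w = ref_weights.weights.get(ref_id, 1)
        node_weight[tid] = node_weight.get(tid, 0) + w
        total += w
    needed = coverage * total
    # accumulate subtree weights along root paths
    cumulative: dict[int, int] = {}
    for tid, w in node_weight.items():
        for anc in tax.path_to_root(tid):
            cumulative[anc] = cumulative.get(anc, 0) + w
    qualifying = [tid for tid, w in cumulative.items() if w >= needed or math.isclose(w, needed)]
    # chain property: sort by depth, verify ancestry while descending
    qualifying.sort(key=tax.depth)
    for shallow, deep in zip(qualifying, qualifying[1:]):
        assert tax.is_ancestor_or_self(shallow, deep), "qualifying nodes must form a chain"
    return ReadAssignment(
        ra.read_id, qualifying[-1], "weighted-lca", score_used=ra.records[0].bitscore
    )


def assignments_to_counts(assignments: Iterable[ReadAssignment]) -> dict[object, int]:
    """Directly-assigned read counts per class (UNASSIGNED kept as a bin)."""
    counts: dict[object, int] = {}
    for a in assignments:
        counts[a.class_id] = counts.get(a.class_id, 0) + 1
    return counts


def min_support_filter(
    assignments: list[ReadAssignment],
    tax: Taxonomy,
    min_support: int = 1,
    min_support_percent: float = 0.0,
) -> list[ReadAssignment]:
    """Promote reads off weakly-supported nodes onto their parents.

    The threshold is ``max(min_support, ceil(min_support_percent *
    assigned-read count))``.  Working deepest-first, any node whose
    on-or-below count falls short has its directly-assigned reads moved
    to its parent; promotions cascade until every populated node (the
    root excepted, having no parent to promote to) meets the threshold.
    """
    assigned = [a for a in assignments if a.assigned]
    threshold = max(min_support, math.ceil(min_support_percent * len(assigned)))
    if threshold <= 1:
        return assignments

    direct: dict[int, list[ReadAssignment]] = {}
    for a in assigned:
        direct.setdefault(a.class_id, []).append(a)

    # subtree counts over populated nodes and their ancestors
    subtree: dict[int, int] = {}
    for tid, reads in direct.items():
        for anc in tax.path_to_root(tid):
            subtree[anc] = subtree.get(anc, 0) + len(reads)

    for tid in sorted(subtree, key=tax.depth, reverse=True):
        if tid == tax.root_id:
            continue
        if 0 < subtree[tid] < threshold:
            movers = direct.pop(tid, [])
            if not movers:
                # support comes from below but was already promoted through
                continue
            parent = tax.parent(tid)
            for a in movers:
                a.class_id = parent
            direct.setdefault(parent, []).extend(movers)
            # counts on-or-below tid drop to zero; ancestors keep the mass
            subtree[tid] -= len(movers)
    return assignments


def _apportion_largest_remainder(total: int, shares: list[tuple[int, float]]) -> dict[int, int]:
    """Split integer *total* over (key, weight) proportionally.

    Largest-remainder integerization; remainder ties broken by ascending
    key so the result is deterministic and conserves *total* exactly.
    """
    weight_sum = sum(w for _, w in shares)
    quotas = [(key, total * w / weight_sum) for key, w in shares]
    floors = {key: int(math.floor(q)) for key, q in quotas}
    leftover = total - sum(floors.values())
    by_remainder = sorted(quotas, key=lambda kq: (-(kq[1] - math.floor(kq[1])), kq[0]))
    for key, _ in by_remainder[:leftover]:
        floors[key] += 1
    return floors


def project_to_rank(
    counts: Mapping[int, int],
    tax: Taxonomy,
    rank: str = "species",
    sample_name: str = "sample",
    parameters: Mapping[str, object] | None = None,
) -> SampleProfile:
    """Project an across-ranks binning onto one fixed rank.

    Counts on nodes at or below *rank* roll up to their ancestor at that
    rank.  Counts on nodes above *rank* are pushed down iteratively: each
    node's count is split among the children carrying nonzero on-or-below
    read mass, proportionally to that mass, integerized by largest
    remainder (remainder ties to the smaller taxon id).  Reads reaching a
    dead end with no path to *rank* land in the UNRESOLVED bin.  The total
    count is conserved exactly.
    """
    profile: dict[object, int] = {}
    unresolved = 0

    # subtree mass of the original binning, for apportionment
    subtree: dict[int, int] = {}
    for tid, c in counts.items():
        if c == 0:
            continue
        if tid not in tax:
            raise KeyError(f"count on unknown taxon {tid}")
        for anc in tax.path_to_root(tid):
            subtree[anc] = subtree.get(anc, 0) + c

    push: dict[int, int] = {}
    for tid, c in counts.items():
        if c == 0:
            continue
        at_rank = ancestor_at_rank(tax, tid, rank)
        if at_rank is not None:
            profile[at_rank] = profile.get(at_rank, 0) + c
        else:
            push[tid] = push.get(tid, 0) + c

    # push down shallow-first so parents distribute before children resolve
    pending = sorted(push, key=tax.depth)
    while pending:
        next_push: dict[int, int] = {}
        for tid in pending:
            amount = push[tid]
            kids = [
                (kid, float(subtree.get(kid, 0)))
                for kid in tax.children.get(tid, [])
                if subtree.get(kid, 0) > 0
            ]
            if not kids:
                unresolved += amount
                continue
            for kid, share in _apportion_largest_remainder(amount, kids).items():
                if share == 0:
                    continue
                at_rank = ancestor_at_rank(tax, kid, rank)
                if at_rank is not None:
                    profile[at_rank] = profile.get(at_rank, 0) + share
                else:
                    next_push[kid] = next_push.get(kid, 0) + share
        push = next_push
        pending = sorted(push, key=tax.depth)

    if unresolved:
        profile[UNRESOLVED] = unresolved
    total = sum(counts.values())
    params = dict(parameters or {})
    params["rank"] = rank
    return SampleProfile(
        sample_name=sample_name,
        classification_name="Taxonomy",
        counts=profile,
        total_reads=total,
        parameters=params,
    )


def functional_bin(ra: ReadAlignments, ref_map: RefClassMap, tree) -> ReadAssignment:
    """Best-hit functional binning against a classification tree.

    Returns the class of the best-bitscore record whose reference
    resolves to a class known to the tree (a node id or an attached
    external id such as an InterPro accession); bitscore ties go to the
    earlier record in the stable descending-score order.
    """
    for rec in ra.records:  # already sorted by descending bitscore, stable
        cid = resolve_class(ref_map, rec.ref_id)
        if cid is not None and tree.knows(cid):
            return ReadAssignment(ra.read_id, cid, "best-hit", score_used=rec.bitscore)
    return ReadAssignment(ra.read_id, UNASSIGNED, "best-hit")
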