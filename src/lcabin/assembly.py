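"""Gene-centric assembly guided by protein alignments.

Reads assigned to one taxonomic or functional class are assembled into
contigs without a de-Bruijn step: each read's best protein alignment to
a reference in the class anchors it on that reference's amino-acid
coordinate system, the anchors imply relative nucleotide offsets between
reads sharing a reference, implied overlaps are verified base-by-base,
and verified overlaps form a graph whose connected placements are merged
greedily (longest, highest-identity overlaps first) into chains.  The
consensus is a per-column majority vote.  Because edges require direct
sequence agreement at high identity, reads from diverged strains do not
join, so individual genes assemble at the strain level.

Coordinate model: an anchored read occupies gene-space nucleotides
``[pos, pos + len(dna))`` with ``pos = 3 * (ref_start - 1) - read_offset``
where *read_offset* is the number of read bases preceding the aligned
region after orientation normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .alignment_io import ReadAlignments, RefClassMap, resolve_class
from .taxonomy import Taxonomy

__all__ = [
    "AnchoredRead",
    "Overlap",
    "OverlapGraph",
    "Contig",
    "anchor_reads",
    "infer_overlaps",
    "extract_contigs",
    "assemble_class",
    "write_contigs_fasta",
]

#: nt slack allowed between read span and 3x the aa span before an
#: alignment is considered frameshifted.
FRAMESHIFT_SLACK = 2


@dataclass
class AnchoredRead:
    read_id: str
    dna: str  # orientation-normalized to the reference frame
    ref_id: str
    ref_start: int  # aa, 1-based inclusive
    ref_end: int
    read_offset: int  # nt before the first aligned base, post-normalization
    frameshift: bool = False

    @property
    def pos(self) -> int:
        """Gene-space nt coordinate of the read's first base."""
        return 3 * (self.ref_start - 1) - self.read_offset

    def __len__(self) -> int:
        return len(self.dna)


@dataclass(frozen=True)
class Overlap:
    u: str  # read ids, u < v lexicographically
    v: str
    implied_shift: int  # pos(v) - pos(u), nt
    overlap_len: int
    identity: float


@dataclass
class OverlapGraph:
    vertices: dict[str, AnchoredRead] = field(default_factory=dict)
    edges: list[Overlap] = field(default_factory=list)


@dataclass
class Contig:
    contig_id: str
    consensus: str
    member_reads: list[tuple[str, int]]  # (read_id, start in contig)
    coverage_profile: list[int]

    def __len__(self) -> int:
        return len(self.consensus)


def anchor_reads(
    class_reads: Sequence[tuple[str, ReadAlignments]],
    ref_map: RefClassMap,
    target_class,
    tax: Taxonomy | None = None,
    diagnostics: dict | None = None,
) -> list[AnchoredRead]:
    """Anchor each read on its best alignment into the target class.

    *class_reads* pairs each read's DNA sequence (as sequenced) with its
    filtered alignments.  An alignment qualifies when its reference
    resolves to the target class — for a taxonomic target with *tax*
    given, to any taxon on or below the target node.  The best-bitscore
    qualifying alignment wins, ties going to the lexicographically
    smaller reference id.  Reverse-orientation reads are
    reverse-complemented so every anchor is forward.
    """
    anchored: list[AnchoredRead] = []
    skipped = 0
    for dna, ra in class_reads:
        best = None
        for rec in ra.records:
            cid = resolve_class(ref_map, rec.ref_id)
            if cid is None:
                continue
            if tax is not None and cid in tax and target_class in tax:
                ok = tax.is_ancestor_or_self(target_class, cid)
            else:
                ok = cid == target_class
            if not ok:
                continue
            if best is None or (rec.bitscore, _neg(rec.ref_id)) > (best.bitscore, _neg(best.ref_id)):
                best = rec
        if best is None:
            skipped += 1
            continue
        seq = dna.upper()
        if best.reverse:
            seq = str(Seq(seq).reverse_complement())
            read_offset = len(seq) - best.read_end
        else:
            read_offset = best.read_start - 1
        aa_span = best.ref_end - best.ref_start + 1
        nt_span = best.read_end - best.read_start + 1
        frameshift = abs(nt_span - 3 * aa_span) > FRAMESHIFT_SLACK
        anchored.append(
            AnchoredRead(
                read_id=ra.read_id,
                dna=seq,
                ref_id=best.ref_id,
                ref_start=best.ref_start,
                ref_end=best.ref_end,
                read_offset=read_offset,
                frameshift=frameshift,
            )
        )
    if diagnostics is not None:
        diagnostics["reads_without_anchor"] = skipped
    return anchored


class _NegStr:
    """Inverts string ordering so max() prefers the smaller ref id."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_NegStr") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s


def _neg(s: str) -> _NegStr:
    return _NegStr(s)


def infer_overlaps(
    anchored: Sequence[AnchoredRead],
    min_overlap_nt: int = 20,
    min_identity: float = 0.98,
) -> OverlapGraph:
    """Verify alignment-implied overlaps and build the overlap graph.

    Reads anchored to the same reference whose amino-acid intervals
    overlap are compared base-by-base over the implied nucleotide span;
    an edge is added iff the span reaches *min_overlap_nt* and the match
    fraction reaches *min_identity*.  Frameshifted anchors are carried
    as vertices but excluded from overlap verification.
    """
    graph = OverlapGraph()
    by_ref: dict[str, list[AnchoredRead]] = {}
    for ar in anchored:
        if ar.read_id in graph.vertices:
            raise ValueError(f"duplicate anchored read {ar.read_id!r}")
        graph.vertices[ar.read_id] = ar
        if not ar.frameshift:
            by_ref.setdefault(ar.ref_id, []).append(ar)
    for ref_id in sorted(by_ref):
        group = sorted(by_ref[ref_id], key=lambda a: a.read_id)
        for i, u in enumerate(group):
            for v in group[i + 1 :]:
                if u.ref_start > v.ref_end or v.ref_start > u.ref_end:
                    continue  # aa intervals disjoint
                lo = max(u.pos, v.pos)
                hi = min(u.pos + len(u), v.pos + len(v))
                span = hi - lo
                if span < min_overlap_nt:
                    continue
                matches = sum(
                    1
                    for x in range(lo, hi)
                    if u.dna[x - u.pos] == v.dna[x - v.pos]
                )
                identity = matches / span
                if identity >= min_identity:
                    graph.edges.append(
                        Overlap(u.read_id, v.read_id, v.pos - u.pos, span, identity)
                    )
    return graph


class _PlacementForest:
    """Union-find with per-read offsets relative to the component root."""

    def __init__(self) -> None:
        self.parent: dict[str, str] = {}
        self.offset: dict[str, int] = {}

    def add(self, rid: str) -> None:
        self.parent.setdefault(rid, rid)
        self.offset.setdefault(rid, 0)

    def find(self, rid: str) -> tuple[str, int]:
        if self.parent[rid] == rid:
            return rid, 0
        root, off = self.find(self.parent[rid])
        self.parent[rid] = root
        self.offset[rid] += off
        return root, self.offset[rid]

    def union(self, u: str, v: str, shift: int) -> bool:
        """Merge so that offset(v) - offset(u) == shift; reject inconsistency."""
        ru, ou = self.find(u)
        rv, ov = self.find(v)
        if ru == rv:
            return ov - ou == shift
        # attach rv under ru: offset of rv := ou + shift - ov
        self.parent[rv] = ru
        self.offset[rv] = ou + shift - ov
        return True


def extract_contigs(graph: OverlapGraph, min_length: int = 200) -> list[Contig]:
    """Greedy chain merging and majority consensus.

    Edges are processed in descending (overlap length, identity) order,
    ties by the vertex-id pair; an edge merges its endpoints' chains when
    the implied placements are mutually consistent (exact shift
    agreement).  Per-column consensus is the majority base, ties going to
    the base of the covering read with the smallest read id.  Contigs
    shorter than *min_length* and singleton reads are dropped.
    """
    forest = _PlacementForest()
    for rid in graph.vertices:
        forest.add(rid)
    for edge in sorted(
        graph.edges, key=lambda e: (-e.overlap_len, -e.identity, e.u, e.v)
    ):
        forest.union(edge.u, edge.v, edge.implied_shift)

    clusters: dict[str, list[tuple[str, int]]] = {}
    for rid in sorted(graph.vertices):
        root, off = forest.find(rid)
        clusters.setdefault(root, []).append((rid, off))

    contigs: list[Contig] = []
    ordered = sorted(clusters.values(), key=lambda members: min(r for r, _ in members))
    serial = 0
    for members in ordered:
        if len(members) < 2:
            continue
        base_off = min(off for _, off in members)
        placed = sorted((rid, off - base_off) for rid, off in members)
        length = max(off + len(graph.vertices[rid].dna) for rid, off in placed)
        if length < min_length:
            continue
        consensus = []
        coverage = []
        for col in range(length):
            votes: dict[str, int] = {}
            readers: list[tuple[str, str]] = []  # (read_id, base)
            for rid, off in placed:
                idx = col - off
                dna = graph.vertices[rid].dna
                if 0 <= idx < len(dna):
                    base = dna[idx]
                    votes[base] = votes.get(base, 0) + 1
                    readers.append((rid, base))
            coverage.append(len(readers))
            if not votes:
                consensus.append("N")  # uncovered gap inside a chain
                continue
            top = max(votes.values())
            tied = {b for b, c in votes.items() if c == top}
            if len(tied) == 1:
                consensus.append(next(iter(tied)))
            else:
                consensus.append(next(b for _, b in sorted(readers) if b in tied))
        serial += 1
        contigs.append(
            Contig(
                contig_id=f"contig_{serial}",
                consensus="".join(consensus),
                member_reads=placed,
                coverage_profile=coverage,
            )
        )
    return contigs


def assemble_class(
    class_reads: Sequence[tuple[str, ReadAlignments]],
    ref_map: RefClassMap,
    target_class,
    tax: Taxonomy | None = None,
    min_overlap_nt: int = 20,
    min_identity: float = 0.98,
    min_length: int = 200,
) -> list[Contig]:
    """anchor -> infer -> extract, deterministic for fixed inputs."""
    anchored = anchor_reads(class_reads, ref_map, target_class, tax=tax)
    graph = infer_overlaps(anchored, min_overlap_nt=min_overlap_nt, min_identity=min_identity)
    return extract_contigs(graph, min_length=min_length)


def write_contigs_fasta(contigs: Iterable[Contig], path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f";{line}\n")
        for c in contigs:
            depth = sum(c.coverage_profile) / len(c.consensus) if c.consensus else 0.0
            fh.write(f">{c.contig_id} len={len(c.consensus)} reads={len(c.member_reads)} cov={depth:.1f}\n")
            for i in range(0, len(c.consensus), 80):
                fh.write(c.consensus[i : i + 80] + "\n")
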