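"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np

from lcabin.alignment_io import AlignmentRecord, ReadAlignments
from lcabin.taxonomy import RANKS, Taxonomy, TaxNode


def build_tax(rows: list[tuple[int, int, str, str]]) -> Taxonomy:
    """Taxonomy from (id, parent, rank, name) rows, no file round-trip."""
    tax = Taxonomy()
    for tid, pid, rank, name in rows:
        tax.nodes[tid] = TaxNode(tid, pid, rank, name)
        if tid == pid:
            tax.root_id = tid
    for tid, node in tax.nodes.items():
        if not node.is_root:
            tax.children.setdefault(node.parent_id, []).append(tid)
    for kids in tax.children.values():
        kids.sort()
    tax.validate()
    return tax


def random_taxonomy(rng: np.random.Generator, n_nodes: int) -> Taxonomy:
    """Random tree over ids 1..n with depth-consistent ranks."""
    rows = [(1, 1, "root", "root")]
    depth = {1: 0}
    for tid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, tid))
        depth[tid] = depth[parent] + 1
        if rng.random() < 0.3:
            rank = "norank"
        else:
            rank = RANKS[min(depth[tid], len(RANKS) - 1)]
        rows.append((tid, parent, rank, f"n{tid}"))
    return build_tax(rows)


def lca_oracle(tax: Taxonomy, ids: set[int]) -> int:
    """Brute force: intersect full ancestor paths, pick the deepest."""
    common = None
    for tid in ids:
        ancestors = set(tax.path_to_root(tid))
        common = ancestors if common is None else common & ancestors
    assert common
    return max(common, key=tax.depth)


def make_record(read_id: str, ref_id: str, bitscore: float, **kw) -> AlignmentRecord:
    defaults = dict(
        percent_identity=95.0,
        align_length=30,
        mismatches=1,
        gap_opens=0,
        read_start=1,
        read_end=90,
        ref_start=10,
        ref_end=39,
        evalue=1e-9,
    )
    defaults.update(kw)
    return AlignmentRecord(read_id=read_id, ref_id=ref_id, bitscore=bitscore, **defaults)


def make_ra(read_id: str, hits: list[tuple[str, float]]) -> ReadAlignments:
    return ReadAlignments(read_id, [make_record(read_id, ref, score) for ref, score in hits])
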