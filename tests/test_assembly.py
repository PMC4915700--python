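import numpy as np
import pytest
from Bio.Seq import Seq

from helpers import build_tax
from lcabin import synth
from lcabin.alignment_io import (
    RefClassMap,
    filter_significant,
    group_by_read,
    parse_tabular,
)
from lcabin.assembly import (
    AnchoredRead,
    anchor_reads,
    assemble_class,
    extract_contigs,
    infer_overlaps,
)


def tiling_world(seed=0, gene_len=600):
    """Single-species world plus error-free reads tiling gene 0."""
    world = synth.make_world(1, 1, 1, genes_per_species=1, gene_len=gene_len, seed=seed)
    species = world.species_ids[0]
    gene = world.genomes[species][0]
    reads = []
    for i, pos in enumerate(range(0, gene_len - 100 + 1, 50)):
        reads.append(
            synth.SimulatedRead(f"read{i}", gene[pos : pos + 100], species, 0, pos, False)
        )
    return world, reads, gene, species


def align_and_group(world, reads, decoy_policy="none"):
    rows = synth.emit_alignments(world, reads, decoy_policy=decoy_policy)
    groups = []
    for ra in group_by_read(parse_tabular(rows)):
        kept = filter_significant(ra)
        if kept:
            groups.append(kept)
    return groups


def class_reads(reads, groups):
    seqs = {r.read_id: r.sequence for r in reads}
    return [(seqs[g.read_id], g) for g in groups]


TAG_MAP = RefClassMap(mode="header-tag", tag="tax")


class TestAnchoring:
    def test_forward_read_unchanged(self):
        world, reads, gene, species = tiling_world()
        groups = align_and_group(world, reads)
        anchored = anchor_reads(class_reads(reads, groups), TAG_MAP, species)
        byid = {a.read_id: a for a in anchored}
        assert byid["read0"].dna == reads[0].sequence
        assert byid["read0"].pos == 0

    def test_reverse_read_normalized_to_forward(self):
        world, reads, gene, species = tiling_world()
        rc = synth.SimulatedRead(
            "rev0", str(Seq(gene[30:130]).reverse_complement()), species, 0, 30, True
        )
        groups = align_and_group(world, [rc])
        anchored = anchor_reads([(rc.sequence, groups[0])], TAG_MAP, species)
        assert anchored[0].dna == gene[30:130]
        assert anchored[0].pos == 30

    def test_taxonomic_target_accepts_descendants(self):
        world, reads, gene, species = tiling_world()
        groups = align_and_group(world, reads)
        genus = world.genus_of(species)
        anchored = anchor_reads(
            class_reads(reads, groups), TAG_MAP, genus, tax=world.taxonomy
        )
        assert len(anchored) == len(reads)

    def test_unanchorable_reads_tallied(self):
        world, reads, gene, species = tiling_world()
        groups = align_and_group(world, reads)
        diag = {}
        anchored = anchor_reads(class_reads(reads, groups), TAG_MAP, 999999, diagnostics=diag)
        assert anchored == [] and diag["reads_without_anchor"] == len(reads)

    def test_best_bitscore_tie_breaks_to_smaller_ref_id(self):
        rows = [
            "r1\tzzz|tax|5\t100.0\t30\t0\t0\t1\t90\t1\t30\t1e-20\t60",
            "r1\taaa|tax|5\t100.0\t30\t0\t0\t1\t90\t1\t30\t1e-20\t60",
        ]
        (group,) = group_by_read(parse_tabular(rows))
        anchored = anchor_reads([("A" * 90, group)], TAG_MAP, 5)
        assert anchored[0].ref_id == "aaa|tax|5"


class TestOverlaps:
    def test_true_overlap_verified(self):
        world, reads, gene, species = tiling_world()
        groups = align_and_group(world, reads)
        anchored = anchor_reads(class_reads(reads, groups), TAG_MAP, species)
        graph = infer_overlaps(anchored, min_overlap_nt=20)
        pair_edges = [e for e in graph.edges if {e.u, e.v} == {"read0", "read1"}]
        assert len(pair_edges) == 1
        edge = pair_edges[0]
        assert edge.identity == 1.0 and edge.overlap_len == 50
        assert abs(edge.implied_shift) == 50

    def test_mismatched_overlap_rejected(self):
        a = AnchoredRead("a", "A" * 60, "ref", 1, 20, 0)
        seq_b = list("A" * 60)
        for i in range(5):
            seq_b[i] = "C"  # 5 mismatches inside the 30 nt overlap
        b = AnchoredRead("b", "".join(seq_b), "ref", 11, 30, 0)  # pos 30
        graph = infer_overlaps([a, b], min_overlap_nt=20, min_identity=0.98)
        assert graph.edges == []

    def test_reads_on_different_references_never_compared(self):
        a = AnchoredRead("a", "A" * 60, "ref1", 1, 20, 0)
        b = AnchoredRead("b", "A" * 60, "ref2", 1, 20, 0)
        assert infer_overlaps([a, b]).edges == []

    def test_short_overlap_skipped(self):
        a = AnchoredRead("a", "A" * 60, "ref", 1, 20, 0)
        b = AnchoredRead("b", "A" * 60, "ref", 16, 35, 0)  # 15 nt overlap
        assert infer_overlaps([a, b], min_overlap_nt=20).edges == []


class TestContigs:
    def test_perfect_tiling_recovers_gene(self):
        world, reads, gene, species = tiling_world()
        groups = align_and_group(world, reads)
        contigs = assemble_class(class_reads(reads, groups), TAG_MAP, species)
        assert len(contigs) == 1
        assert contigs[0].consensus == gene
        assert len(contigs[0].member_reads) == len(reads)
        assert min(contigs[0].coverage_profile) >= 1

    def test_empty_graph_empty_list(self):
        assert extract_contigs(infer_overlaps([])) == []

    def test_singletons_never_emitted(self):
        a = AnchoredRead("a", "A" * 300, "ref", 1, 100, 0)
        assert extract_contigs(infer_overlaps([a]), min_length=100) == []

    def test_min_length_filter(self):
        world, reads, gene, species = tiling_world()
        groups = align_and_group(world, reads)
        contigs = assemble_class(
            class_reads(reads, groups), TAG_MAP, species, min_length=10_000
        )
        assert contigs == []

    def test_two_haplotypes_stay_separate(self):
        # two species of one genus, ~10% divergent genes; no cross-strain contig
        world = synth.make_world(1, 1, 2, 1, 600, seed=5)
        s1, s2 = world.species_ids
        reads = []
        for species in (s1, s2):
            gene = world.genomes[species][0]
            for i, pos in enumerate(range(0, 501, 50)):
                reads.append(
                    synth.SimulatedRead(
                        f"sp{species}r{i}", gene[pos : pos + 100], species, 0, pos, False
                    )
                )
        groups = align_and_group(world, reads, decoy_policy="same-genus")
        seqs = {r.read_id: r.sequence for r in reads}
        genus = world.genus_of(s1)
        contigs = assemble_class(
            [(seqs[g.read_id], g) for g in groups], TAG_MAP, genus, tax=world.taxonomy
        )
        assert len(contigs) == 2
        recovered = sorted(c.consensus for c in contigs)
        truth = sorted([world.genomes[s1][0], world.genomes[s2][0]])
        assert recovered == truth
        for c in contigs:
            strains = {rid.split("r")[0] for rid, _ in c.member_reads}
            assert len(strains) == 1  # label purity

    def test_determinism(self):
        world, reads, gene, species = tiling_world()
        groups = align_and_group(world, reads)

        def run():
            return assemble_class(class_reads(reads, groups), TAG_MAP, species)

        a, b = run(), run()
        assert [(c.contig_id, c.consensus, c.member_reads) for c in a] == [
            (c.contig_id, c.consensus, c.member_reads) for c in b
        ]

    def test_members_realign_to_consensus(self):
        # soundness: each member read matches the consensus at its placement
        world = synth.make_world(1, 1, 1, 1, 600, seed=9)
        species = world.species_ids[0]
        reads = synth.simulate_reads(world, 80, 100, error_rate=0.005, seed=2)
        groups = align_and_group(world, reads)
        seqs = {r.read_id: r.sequence for r in reads}
        contigs = assemble_class(
            [(seqs[g.read_id], g) for g in groups], TAG_MAP, species, tax=world.taxonomy
        )
        assert contigs
        for c in contigs:
            for rid, start in c.member_reads:
                read_fwd = c.consensus[start : start + 100]
                placed = next(
                    a for a in (seqs[rid], str(Seq(seqs[rid]).reverse_complement()))
                    if sum(x == y for x, y in zip(a, read_fwd)) / len(read_fwd) >= 0.95
                )
                assert placed is not None
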