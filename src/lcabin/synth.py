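"""Fully-labelled synthetic fixtures: taxonomy, genes, references, reads,
alignment tables, mapping files and metadata.

The generator emulates a small shotgun-metagenome experiment end to end
so the whole pipeline is testable without downloads.  A balanced
taxonomy ladder (root -> phylum -> genus -> species) is populated with
gene sequences that diverge by per-site substitution: each genus derives
its genes from a phylum ancestor (20% divergence by default), each
species from its genus ancestor (5% by default) — values in the range
separating bacterial congeners and confamilials.  Every species gene is
translated into a protein reference whose id embeds a ``tax|<id>`` tag,
so the header-tag resolution mechanism is exercised verbatim.  Reads are
uniform substrings with uniform strand and per-base substitution errors;
alignments are produced by an oracle aligner that scores exact
translated comparisons at the known offset (match +2 / mismatch -1)
rather than by a heuristic search, writing the standard 12-column
tabular dialect.  All emitters are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio.Seq import Seq

from .taxonomy import Taxonomy, TaxNode

__all__ = [
    "SyntheticWorld",
    "SimulatedRead",
    "make_world",
    "simulate_reads",
    "emit_alignments",
    "taxonomy_tsv",
    "reads_fastq",
    "truth_tsv",
    "metadata_csv",
    "functional_map_tsv",
]

_BASES = np.array(list("ACGT"))
#: codons that avoid in-frame stops when genes are first synthesized
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str  # as sequenced (reverse reads already complemented)
    true_taxon: int
    gene_index: int
    position: int  # 0-based nt offset of the forward segment on the gene
    reverse: bool


@dataclass
class SyntheticWorld:
    taxonomy: Taxonomy
    #: species taxon id -> gene nucleotide sequences (index-aligned across taxa)
    genomes: dict[int, list[str]]
    #: ref id -> (protein sequence, species taxon id, functional class id)
    references: dict[str, tuple[str, int, str]]
    gene_len: int
    params: dict[str, object] = field(default_factory=dict)

    @property
    def species_ids(self) -> list[int]:
        return sorted(self.genomes)

    def ref_id(self, species: int, gene_index: int) -> str:
        return f"sp{species}g{gene_index}|tax|{species}"

    def genus_of(self, species: int) -> int:
        return self.taxonomy.parent(species)


def _random_gene(rng: np.random.Generator, gene_len: int) -> str:
    codons = []
    while len(codons) * 3 < gene_len:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)[:gene_len]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def make_world(
    n_phyla: int = 2,
    n_genera_per: int = 2,
    n_species_per: int = 3,
    genes_per_species: int = 3,
    gene_len: int = 600,
    seed: int = 0,
    species_divergence: float = 0.05,
    genus_divergence: float = 0.20,
) -> SyntheticWorld:
    """Deterministically build a labelled world.

    Sizes must be positive and *gene_len* divisible by 3.  The default
    world stays small (<= 60 taxa) so full-pipeline tests run in seconds.
    """
    if min(n_phyla, n_genera_per, n_species_per, genes_per_species, gene_len) < 1:
        raise ValueError("all world sizes must be positive")
    if gene_len % 3:
        raise ValueError("gene_len must be divisible by 3")
    rng = np.random.default_rng(seed)

    tax = Taxonomy()
    tax.nodes[1] = TaxNode(1, 1, "root", "root")
    tax.root_id = 1
    next_id = 2
    genomes: dict[int, list[str]] = {}
    references: dict[str, tuple[str, int, str]] = {}

    for _ in range(n_phyla):
        phylum = next_id
        next_id += 1
        tax.nodes[phylum] = TaxNode(phylum, 1, "phylum", f"Phylum_{phylum}")
        phylum_genes = [_random_gene(rng, gene_len) for _ in range(genes_per_species)]
        for _ in range(n_genera_per):
            genus = next_id
            next_id += 1
            tax.nodes[genus] = TaxNode(genus, phylum, "genus", f"Genus_{genus}")
            genus_genes = [_mutate(rng, g, genus_divergence) for g in phylum_genes]
            for _ in range(n_species_per):
                species = next_id
                next_id += 1
                tax.nodes[species] = TaxNode(species, genus, "species", f"Species_{species}")
                genes = [_mutate(rng, g, species_divergence) for g in genus_genes]
                genomes[species] = genes

    for node in tax.nodes.values():
        if not node.is_root:
            tax.children.setdefault(node.parent_id, []).append(node.taxon_id)
    for kids in tax.children.values():
        kids.sort()
    tax.validate()

    world = SyntheticWorld(
        taxonomy=tax,
        genomes=genomes,
        references={},
        gene_len=gene_len,
        params={
            "n_phyla": n_phyla,
            "n_genera_per": n_genera_per,
            "n_species_per": n_species_per,
            "genes_per_species": genes_per_species,
            "gene_len": gene_len,
            "seed": seed,
            "species_divergence": species_divergence,
            "genus_divergence": genus_divergence,
        },
    )
    for species, genes in genomes.items():
        for gi, gene in enumerate(genes):
            protein = str(Seq(gene).translate())
            references[world.ref_id(species, gi)] = (protein, species, f"FAM{gi:03d}")
    world.references = references
    return world


def simulate_reads(
    world: SyntheticWorld,
    n_reads: int = 1000,
    read_len: int = 100,
    error_rate: float = 0.01,
    seed: int = 0,
    abundance: dict[int, float] | None = None,
) -> list[SimulatedRead]:
    """Sample reads uniformly over (species, gene, position, strand).

    Per-base substitution errors at *error_rate*; *abundance* optionally
    skews the species sampling weights (normalized internally).
    """
    if read_len > world.gene_len:
        raise ValueError("read_len exceeds gene_len")
    rng = np.random.default_rng(seed)
    species_ids = world.species_ids
    if abundance:
        w = np.array([abundance.get(s, 0.0) for s in species_ids], dtype=float)
        if w.sum() <= 0:
            raise ValueError("abundance weights sum to zero")
        probs = w / w.sum()
    else:
        probs = np.full(len(species_ids), 1.0 / len(species_ids))
    reads = []
    for i in range(n_reads):
        species = int(rng.choice(species_ids, p=probs))
        gi = int(rng.integers(len(world.genomes[species])))
        pos = int(rng.integers(world.gene_len - read_len + 1))
        segment = world.genomes[species][gi][pos : pos + read_len]
        segment = _mutate(rng, segment, error_rate) if error_rate > 0 else segment
        reverse = bool(rng.integers(2))
        seq = str(Seq(segment).reverse_complement()) if reverse else segment
        reads.append(SimulatedRead(f"read{i}", seq, species, gi, pos, reverse))
    return reads


def _oracle_hit(
    read: SimulatedRead, gene: str, ref_id: str, match: int, mismatch: int
) -> str | None:
    """One 12-column row for the exact translated comparison, or None."""
    pos, L = read.position, len(read.sequence)
    c0 = math.ceil(pos / 3)
    c1 = (pos + L) // 3 - 1
    if c1 < c0 + 4:  # require >=5 complete codons
        return None
    forward = (
        str(Seq(read.sequence).reverse_complement()) if read.reverse else read.sequence
    )
    read_aa = str(Seq(forward[3 * c0 - pos : 3 * (c1 + 1) - pos]).translate())
    ref_aa = str(Seq(gene).translate())[c0 : c1 + 1]
    matches = sum(1 for a, b in zip(read_aa, ref_aa) if a == b)
    aa_len = c1 - c0 + 1
    score = match * matches + mismatch * (aa_len - matches)
    if score <= 0:
        return None
    pident = 100.0 * matches / aa_len
    qstart = 3 * c0 - pos + 1
    qend = qstart + 3 * aa_len - 1
    if read.reverse:
        qstart, qend = L - qstart + 1, L - qend + 1  # start > end encodes reverse
    evalue = 10.0 ** (-score / 4.0)
    return "\t".join(
        [
            read.read_id,
            ref_id,
            f"{pident:.1f}",
            str(aa_len),
            str(aa_len - matches),
            "0",
            str(qstart),
            str(qend),
            str(c0 + 1),
            str(c1 + 1),
            f"{evalue:.2e}",
            f"{float(score):g}",
        ]
    )


def emit_alignments(
    world: SyntheticWorld,
    reads: Iterable[SimulatedRead],
    match: int = 2,
    mismatch: int = -1,
    decoy_policy: str = "same-genus",
) -> list[str]:
    """Oracle alignment rows (12-column tabular, read-contiguous).

    Each read is compared against its true reference and, per
    *decoy_policy* (``none`` / ``same-genus`` / ``all``), against the
    homologous gene of sibling species or of every species.  Scores come
    from exact translated comparison at the known offset, so decoys at
    5% divergence score strictly below a low-error true hit.
    """
    if decoy_policy not in ("none", "same-genus", "all"):
        raise ValueError(f"unknown decoy policy {decoy_policy!r}")
    rows: list[str] = []
    for read in reads:
        candidates: list[int]
        if decoy_policy == "none":
            candidates = [read.true_taxon]
        elif decoy_policy == "same-genus":
            genus = world.genus_of(read.true_taxon)
            candidates = [
                s for s in world.species_ids if world.genus_of(s) == genus
            ]
        else:
            candidates = world.species_ids
        hits = []
        for species in candidates:
            gene = world.genomes[species][read.gene_index]
            row = _oracle_hit(
                read, gene, world.ref_id(species, read.gene_index), match, mismatch
            )
            if row is not None:
                hits.append(row)
        hits.sort(key=lambda r: -float(r.split("\t")[11]))
        rows.extend(hits)
    return rows


# ---------------------------------------------------------------------------
# plain-text emitters


def taxonomy_tsv(world: SyntheticWorld) -> str:
    lines = [
        f"{n.taxon_id}\t{n.parent_id}\t{n.rank}\t{n.name}"
        for n in sorted(world.taxonomy.nodes.values(), key=lambda n: n.taxon_id)
    ]
    return "\n".join(lines) + "\n"


def reads_fastq(reads: Iterable[SimulatedRead], quality: str = "I") -> str:
    chunks = []
    for r in reads:
        chunks.append(f"@{r.read_id}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")
    return "".join(chunks)


def truth_tsv(reads: Iterable[SimulatedRead]) -> str:
    lines = ["#read_id\ttaxon_id\tgene_index\tposition\tstrand"]
    for r in reads:
        strand = "-" if r.reverse else "+"
        lines.append(f"{r.read_id}\t{r.true_taxon}\t{r.gene_index}\t{r.position}\t{strand}")
    return "\n".join(lines) + "\n"


def functional_map_tsv(world: SyntheticWorld) -> str:
    """2-column (ref token, functional class) mapping table."""
    lines = [
        f"{rid}\t{fam}" for rid, (_, _, fam) in sorted(world.references.items())
    ]
    return "\n".join(lines) + "\n"


def metadata_csv(sample_names: list[str], seed: int = 0) -> str:
    """Toy per-sample metadata: subject, day and a numeric measurement."""
    rng = np.random.default_rng(seed)
    lines = ["#SampleID,subject,day,measurement"]
    for i, name in enumerate(sample_names):
        subject = "A" if i % 2 == 0 else "B"
        day = i * 3
        measurement = float(np.round(rng.normal(10.0, 2.0), 3))
        lines.append(f"{name},{subject},{day},{measurement}")
    return "\n".join(lines) + "\n"
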