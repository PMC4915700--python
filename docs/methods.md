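# Methods

This note documents the models and procedures implemented in `lcabin`,
the parameters that matter, the numerical choices, what the synthetic
data generator does and does not emulate, and known limitations.

## Taxonomy model

The taxonomy is a rooted tree of integer-id nodes with a fixed ordered
rank vocabulary (root, domain, phylum, class, order, family, genus,
species, strain). A node is the root iff its parent id equals its own
id, matching the NCBI dump convention (node 1). Unknown rank strings
(NCBI dumps carry dozens of intermediate ranks) are coerced to `norank`,
which is transparent to rank queries: `ancestor_at_rank` walks rootward
from a node (inclusive) and returns the first node whose rank matches.
Both the NCBI `nodes.dmp`/`names.dmp` pipe-delimited dialect and a plain
4-column TSV are accepted, auto-detected by delimiter; when a taxon has
several names the "scientific name" class wins. LCA is computed by
trimming the first member's root path against each further member's
ancestor set; correctness is pinned against a brute-force
path-intersection oracle on random trees in the test suite.

## Significance filtering

Aligners report many marginal hits per read, so binning operates on a
filtered alignment set: bitscore ≥ `minScore` (default 50), e-value ≤
`maxExpected` (default 0.01), percent identity ≥ `minPercentIdentity`
(default 0, i.e. off), and then a relative gate keeping hits with
bitscore ≥ (1 − `topPercent`/100) × the best *surviving* score (default
10%). Applying the relative gate after the absolute ones makes the
filter idempotent and the two gates order-independent in effect. The
defaults are the conventional ones for protein-alignment binning; they
are configurable and echoed into every output header.

Reverse-strand alignments (query start > query end in the tabular
input) are normalized on parsing — coordinates swapped, an orientation
flag set — and restored byte-compatibly on serialization. Coordinates
stay 1-based inclusive throughout; only the assembler converts
internally to a 0-based gene-space axis.

## Naive and weighted LCA

The naive rule assigns a read to the LCA of every taxon its surviving
alignments resolve to. Resolution is rank-agnostic: a reference mapped
to a genus-level taxon participates as that taxon. Unresolvable records
are dropped (tallied); a read with none is UNASSIGNED.

The weighted rule runs in two passes over the sample. Pass 1: for each
read whose resolved references all share one *species assignment* (the
species-rank ancestor of the reference's taxon, falling back to the
taxon itself when no species ancestor exists), the weight of every one
of its references is incremented; reads spanning two or more species
contribute nothing. Afterwards every reference seen in a surviving
alignment is floored to weight 1 — without the floor, reads aligning
only to ambiguous references would carry total weight 0 and be
unplaceable. Pass 2: with W the summed weight of a read's references,
the read is placed on the deepest node whose subtree holds ≥ c·W,
c = 0.75 by default. c must exceed 0.5; the implementation asserts the
chain property of the qualifying set during traversal. Weights count
every surviving alignment of a read, not only the best-scoring ones.

## Rank projection

Counts on nodes at or below the target rank roll up via
`ancestor_at_rank`. Counts above it are pushed down breadth-first: a
node's count is split among the children carrying nonzero original
(on-or-below) read mass, proportionally to that mass. Integerization is
by largest remainder with remainder ties broken by ascending taxon id —
chosen for exact conservation plus determinism. Counts reaching a node
with no counted path to the target rank (a leaf above the rank, or a
`norank` branch with no ranked descendant carrying mass) land in an
UNRESOLVED bin, so the projected total always equals the input total
exactly, which the tests verify on random tree/count configurations.

A node counts as "below the rank" iff `ancestor_at_rank` (inclusive)
succeeds on it; everything else enters the push-down path. The
min-support filter (off by default: `minSupport=1`,
`minSupportPercent=0`) promotes reads deepest-first off nodes whose
on-or-below count falls short of
max(minSupport, ⌈minSupportPercent × assigned⌉); the root is exempt,
having no parent to promote to. Filtering precedes projection.

## Functional classification

A generic classification tree (3-column TSV: id, parent or ROOT, label)
carries SEED-like and eggNOG-like hierarchies; every node id is
binnable, inner nodes included, and reads are assigned by best bit
score among records resolving into the tree (score ties to the earlier
record in the stable descending order). No SEED/eggNOG/KEGG content is
shipped — those are external, versioned resources; only the carriers
are provided.

The InterPro2GO builder reduces each family's GO annotations per GO
domain to the slim terms reachable through a supplied ancestry mapping
(a slim term is its own ancestor). Exactly one slim term in a domain
places the family under that term; two or more place it under a lazily
created `<domain>:Other` node; no usable annotation places it under
"Unclassified". The ancestry mapping is an explicit input rather than a
parsed OBO ontology, keeping the module download-free; GO terms with no
slim ancestor anywhere are ignored for placement and tallied. Family
node ids are `<parent>::<accession>`, so a family placed in several
domains yields distinct nodes all carrying the accession as payload;
roll-ups credit the full read count to every placement, so tier-1 sums
can exceed the classified-read total — consumers of the per-node counts
must carry the multi-counting caveat forward. Layout order is fixed by
lexicographic sorting, so rebuilding from the same inputs is identical.

## Comparison and ecology

The comparison document is a classes × samples matrix (absent cells are
0) with a merged metadata table keyed by sample. Normalization scales
every sample to the smallest classified total (idempotent; a
zero-total sample is an error naming the sample). Core biome presence
means count ≥ `detection_min` (default 1 — "appears in" is deliberately
an explicit knob) in ≥ ⌈fraction × samples⌉ samples. Grouping by a
metadata attribute sums counts within each value, absent values forming
an "NA" group.

Distances operate on the matrix exactly as given; normalization is the
caller's explicit step, avoiding hidden state. Jensen–Shannon uses the
natural logarithm (distance bounded by √ln 2). PCoA double-centers the
squared distances, eigendecomposes with a symmetric solver, scales
eigenvectors by √eigenvalue, and fixes each axis's sign by forcing its
largest-magnitude coordinate positive, making output reproducible
across eigensolvers (the test suite cross-checks against an independent
PCoA implementation and against PCA on Euclidean input). Negative
eigenvalues from non-Euclidean distances are excluded from the variance
fractions with a logged warning; k is truncated to the available
positive axes.

Bi-plot vectors: component j of a class's vector is the Pearson
correlation between the class's per-sample *relative abundances* and
the axis-j coordinates, scaled by the class's share of the total
standard deviation; classes rank by vector length (ties by ascending
id) and the top five are reported by default. Zero-variance classes are
excluded. Tri-plots apply the same construction to numeric metadata
attributes; non-numeric attributes are skipped with a note. The
magnitude convention (correlation × std-dev share) is this package's
choice of a scale for "direction of steepest increase" and is pinned in
tests.

Alpha diversity: Shannon −Σ pᵢ ln pᵢ, Gini–Simpson 1 − Σ pᵢ², richness
as support size; the registry is extensible.

## Gene-centric assembly

Anchoring: a read's best-bitscore alignment to a reference resolving
into the target class (on-or-below the node, for taxonomic targets)
fixes the read on that reference's amino-acid axis; ties go to the
lexicographically smaller reference id. Reverse reads are
reverse-complemented so all anchors are forward. The read's gene-space
position is 3·(ref_start − 1) − read_offset, with read_offset the
number of read bases preceding the aligned region.

Overlaps are only considered between reads anchored to the same
reference (merging across different reference proteins of one family is
a known divergence candidate, deliberately not done); the implied shift
is the difference of gene-space positions, and the candidate span is
verified base-by-base: an edge requires span ≥ 20 nt and identity
≥ 0.98 by default. Alignments whose read span differs from 3× the
amino-acid span by more than 2 nt are treated as frameshifted: they are
anchored (and can join a contig through their cluster) but excluded
from overlap verification, avoiding indel-induced spurious shifts.

Contig extraction processes edges in descending (overlap length,
identity) order, ties by vertex ids, through a union–find that tracks
each read's offset to its component root; an edge joining one component
to itself must agree exactly with the established offsets (0 nt
tolerance) or it is skipped, and a cross-component edge merges with the
implied translation. Consensus is per-column majority, ties resolved by
the base of the covering read with the smallest read id; uncovered
interior columns (possible only via frameshifted members) emit N.
Contigs shorter than 200 nt (default) and singleton reads are not
emitted. The per-read placements and greedy order are fully
deterministic, so identical inputs give byte-identical FASTA.

The overall pipeline — anchor by best hit, shift formula, verification
thresholds, greedy merging, majority consensus — is this package's
concrete completion of protein-alignment-guided overlap assembly, with
every constant exposed as a parameter. Because cross-strain edges fail
the identity gate once divergence exceeds (1 − min_identity) over the
overlap span, strains assemble separately, which the two-haplotype
simulation verifies by label purity.

## Synthetic data generator

The generator emulates the study conditions end to end: a balanced
root → phylum → genus → species ladder; per-gene ancestor sequences per
phylum; genera diverged from the phylum ancestor at 20% per site and
species from their genus at 5% — between-congener / between-confamilial
distances typical of bacterial protein-coding genes; species genes
translated into protein references whose ids embed a `tax|<id>` header
tag. Reads are uniform substrings (default 100 nt, matching short-read
experiments) with uniform strand and per-base substitution errors
(default 1%); the truth table records species, gene, position and
strand for every read. Alignments come from an *oracle aligner* —
exact translated comparison at the known offset, scored match +2 /
mismatch −1, e-value a monotone function of score — rather than a
heuristic search, which removes any aligner dependency while exercising
the exact 12-column file dialect, read-contiguity and reverse-strand
coordinate conventions.

What the generator does **not** emulate: indels and frameshifts,
quality-score structure, chimeras, conserved-vs-variable site structure
within genes, horizontal transfer, incomplete or mislabeled reference
databases, and alignment heuristics' false positives/negatives. Passing
tests therefore demonstrate the correctness of the binning, projection,
ordination and assembly logic under clean, fully-labelled conditions —
not end-to-end accuracy on real data, where alignment noise and
reference bias dominate.

Default problem sizes (worlds of ≤ 60 taxa, ≤ a few thousand reads,
600 nt genes) were chosen so the full suite and the acceptance script
each complete in seconds while still exercising multi-phylum,
multi-genus ambiguity; all emitters are pure functions of
(parameters, seed).

## Known limitations

- Long reads: the LCA rules treat a read as one unit; no interval-based
  assignment along the read.
- Paired ends are not linked in binning or assembly.
- The weighted LCA weights every surviving alignment of a read; whether
  to restrict weighting to best-scoring hits is a documented open choice,
  pinned by tests.
- The assembler requires a shared reference per overlap and exact offset
  consistency; structural variants between strains fragment contigs
  rather than producing chimeras (by design).
- Taxonomy is an input, never bundled; merged/deleted-node remapping
  files are not handled.
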