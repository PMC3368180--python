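# Methods

This note documents the models and procedures implemented in
`rgene_atlas`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate about real data.

## Domain detection

### NBS motifs

NBS domains are called from a fixed library of twenty degenerate consensus
motifs shipped in `data/motifs.tsv`. Eight carry the canonical NBS labels
(P-loop: motifs 2 and 9; RNBS-A: 14; Kinase-2: 7 and 18; RNBS-B: 10 and
20; RNBS-C: 19; GLPL: 3 and 15; RNBS-D: 1; MHDV: 6); motif 8 is the
CC-associated N-terminal motif containing Q(L/I/V)RD. Motif 4 also
resembles an RNBS-C consensus but is not on the canonical label map, which
follows the restricted motif-to-label assignment above; it still
participates in scanning as an unlabelled motif.

A window hits a motif when its overall mismatch fraction is at most
`max_mismatch_fraction` (default **0.4**) and, where the motif declares a
conserved core (the most invariant residues of the consensus), the core
carries at most **1** mismatch. The 0.4 budget is a package design choice:
consensus strings are "best possible match" representatives, and family
members diverge around them; 0.4 recovers the generator's mutated motif
instances (20–25% diverged) while the probability that a random 20-letter
window satisfies both the budget and the core constraint is negligible
(< 1e-6 per window; the generator's rejection screening would catch any
residual collision). The per-label best hit maximises matched fraction,
breaking ties by earlier position and then lower motif id.

An NBS domain is present iff **≥ 5** of the eight canonical labels hit and
the best hits of the labels found occur in the canonical order (strictly
increasing start positions, order restricted to the labels present). The
NBS span runs from the first found motif start to the last found motif
end; a second complete motif series downstream of the first span is
reported as a second NBS block (the atypical CNNL arrangement).

### LRR

Non-overlapping matches of the 11-residue consensus LxxLxLxxNxL are
counted greedily left-to-right from the end of the NBS span (or from the
N-terminus when no NBS is present). The 'L' positions accept the aliphatic
set {L, I, V, M, F, A} — the consensus demands "leucine or another
aliphatic residue" without enumerating, so the set is a documented,
configurable choice — and the 'N' position accepts {N, T, S, C}. Two
repeats make an LRR domain.

### Coiled-coil

Windows of 28 residues (14 and 21 available for short sequences) are
scored as weighted geometric means of per-residue heptad propensities
(`data/coils_propensities.tsv`), with the hydrophobic-core registers *a*
and *d* weighted 2.5 and all seven register phases tried. The score is
converted to a probability through two Gaussians,
P = G_cc/(G_cc + w·G_glob) with w = 1; the Gaussian means/SDs per window
size are this package's calibration of the score distributions (globular
windows centre near 0.8, coiled-coil windows near 1.9 at window 28). A CC
is called when ≥ 14 consecutive residues have probability ≥ 0.9 (default
threshold). An N-terminal CC for classification additionally accepts a hit
of motif 8 or of Q(L/I/V)RD (exact match); in all cases the evidence must
start before the NBS span.

## Classification

*Regular* status combines two criteria: an NBS domain (the ≥ 5-motifs-in-
order rule) **and** a similarity filter against a reference R-protein set —
best alignment covering **≥ 70%** of the longer sequence at **≥ 50%**
identity, both inclusive. References are ranked by raw alignment score
(the BLAST best-hit convention) and the stats are computed from the full
alignment against the top-ranked reference. Genes whose motif content
falls below the 5-motif rule but retain ≥ 3 canonical motifs are kept as
nonregular NBS genes (the floor of 3 is a documented package choice; no
numeric cutoff exists for "too divergent").

Letter codes from the ordered domain list: CC+NBS+LRR → CNL; NBS+LRR
(no CC, with or without an unknown X N-terminus) → NL; CC+NBS → CN;
X+NBS → XN; two NBS blocks with CC and LRR → CNNL-atypical; bare NBS → N.
The X label is a fallback: it is recorded when no CC is detected and at
least 10 residues precede the NBS span, never positively detected.

## Pairwise alignment

All protein-protein coverage/identity statistics come from global
alignment with free terminal gaps (BLOSUM62, gap open 10, extend 1 — a
community default, configurable). Coverage is the aligned (non-terminal-
gap) span measured on the longer sequence divided by its length; identity
is matches over aligned columns excluding terminal gaps. The all-vs-all
stage uses a score-only prefilter (skip pairs scoring below 0.25 × the
smaller self-score); the floor is far below any score a pair satisfying
the >70%/>70% duplication criterion can have, and a regression test
verifies filtered and unfiltered event sets coincide.

## Duplications and families

A duplication event requires coverage **> 70%** and identity **> 70%**
(strict — deliberately distinct from the inclusive regular-gene filter;
a regression test keeps the two from interchanging). "Tightly linked"
genes are those on one chromosome with starts within `tandem_distance`
(default 200 kb, reusing the cluster window); within each mutually-linked
tandem component only genomically adjacent pairs are retained, so an array
of k similar genes contributes k−1 events. Families are single-linkage
connected components of the event graph (the construction used for the
published family counts is not stated; single linkage is the choice here)
with at least two members. Summary statistics follow the conventional
table formatting: percentages to 1 decimal, ratios to 2 decimals, average
members per family = multigene genes / families. Family-member pairs on
different chromosomes are flagged as candidate segmental duplications.

## Genomic clusters

A gene belongs to a cluster iff it lies in at least one window of width
`window_size` (default 200 kb) containing ≥ `min_genes` (default 4) genes.
Gene position is the start coordinate and windows are measured
start-to-start, inclusive — the simplest reading of the "four or more
genes within 200 kb" definition; midpoint anchoring would shift boundaries
by half a gene length and is not used. Windows anchored at each gene are
exhaustive (any qualifying window can slide left onto a gene start without
losing genes), and overlapping qualifying windows merge into maximal
clusters. Superclusters use the same machinery at 430 kb with a
min-genes floor of 8. Membership is monotone in window size and
anti-monotone in min_genes (property-tested), and equals a brute-force
window enumeration oracle.

## Promoters

The 2-kb region immediately upstream of the annotated gene start (strand-
aware, reverse-complemented for minus-strand genes, truncated at
chromosome ends) is scanned for WBOX = TGACY, CBF = GTCGAC and
GCC = GCCGCC with IUPAC matching. No GCC-box consensus is stated anywhere
authoritative for this workflow; GCCGCC, the canonical ERF-binding box, is
adopted and documented as an assumption. Both strands are counted by
default (single-strand available), overlapping occurrences all count, the
palindromic CBF consensus is collapsed so + and − matches at one position
count once, and windows containing N never match. Summaries report means
to 2 decimals, the share of genes with ≥ 11 WBOX, and the share containing
all three element types.

## Phylogeny

Distances: Kimura two-parameter for aligned nucleotide sequences,
d = −½·ln[(1−2P−Q)·√(1−2Q)] with P/Q the transition/transversion
fractions over pairwise-complete sites; Poisson correction d = −ln(1−p)
for proteins. Applying a nucleotide model to amino-acid alignments is not
meaningful, so the protein default is Poisson and K2P is offered for CDS
alignments — the one place this package deliberately departs from the
workflow it re-implements. Saturated pairs (log-domain boundary) raise a
flagged error rather than returning infinity.

Neighbor joining is the standard Saitou–Nei agglomeration with
deterministic lexicographic tie-breaking and negative branch lengths
clamped to zero with a warning. Bootstrap resamples columns with
replacement; an internal edge's support is the percentage of replicate
trees containing the same bipartition; everything is reproducible from the
seed (CLI default 1000 replicates, the pipeline default is 100). A
simplified conserved-block filter (drop columns with > 50% gaps or modal
residue fraction < 50%) stands in for full alignment curation.

Multiple alignment itself is out of scope. The pipeline builds its tree
from the detected NBS spans, which the generator makes equal-length across
regular genes (one fixed genome-wide template of inter-motif linker
lengths), so the spans align column-wise without an aligner; on real data
the `tree` subcommand consumes an externally computed alignment.

## EST support

An EST supports a gene when a local alignment of ≥ 100 bp at ≥ 90%
identity exists on either strand. The 90% threshold is the stated
criterion; the 100-bp overlap floor is a package choice (a threshold on
identity alone is ill-posed for arbitrarily short alignments) and is
configurable. Matching is BLAST-like: exact 11-mer seeds define candidate
diagonals; diagonals are merged at band resolution, kept only with ≥ 2
seeds (two-hit rule — a genuine qualifying alignment carries ~10
co-diagonal seeds in expectation, stray single-seed collisions between
paralogs' codon runs are skipped), ranked by seed support, capped at 8 per
pair, and extended by banded local dynamic programming (band ± 15, match
+1, mismatch −2, gap −2.5, linear gaps so each DP row vectorises).
Identity is matches over alignment columns of the best-scoring local
alignment, matching an unseeded Smith–Waterman oracle's decisions on
random instances (tested). By default an EST counts for every gene it
matches, mirroring database-search semantics; best-hit-only assignment
(ties broken by alignment length then gene id) is available and is what
planted-count recovery is asserted under, since close paralogs can
legitimately share ESTs.

## Synthetic genomes and what the tests show

The generator's defaults are the study conditions the analysis is
validated under: 5 chromosomes of 8 Mb; 126 regular genes in quota
proportions 102 CNL : 12 NL : 11 CN : 1 XN plus 14 nonregular and 10
background genes; 20 families (sizes 7, 4, 3, 3 and sixteen pairs = 49
genes, two pairs split across chromosomes as segmental duplicates); 11
clusters (two of 7 genes, nine of 4) on chromosomes 1, 2 and 4 only;
isolated genes spaced ≥ 210 kb so no spurious clusters arise; promoter
element counts Poisson with means (17.10, 3.36, 2.01); EST coverage
1 + Poisson(2) per supported gene with 2% read error, and exactly 8% of
regular genes (chosen among singletons) left without ESTs.

Construction guarantees exact recovery ("collision screening"): promoter
background is regenerated until no element consensus matches on either
strand and planted instances are re-scanned to exact counts; protein
linkers, N-termini and family point mutations are rejection-sampled so
that each protein's detected architecture equals its intended one; family
mutations never touch planted motif, CC or LRR positions, and each family
ancestor carries its own 20%-diverged motif instances so between-family
identity (~0.4–0.5) sits far below the 0.70 event threshold while
within-family identity (~0.9) sits far above it. Coding sequences choose
synonymous codons independently per gene, decorrelating paralogs at the
nucleotide level (~0.8 identity) so ESTs distinguish siblings at the 90%
criterion. One nonregular gene flavour carries only four canonical motifs,
the other all eight in a shuffled order.

Passing tests therefore show the implementation is *correct against its
definitions* and recovers structure whose signal/threshold margins are
generous. They do not show robustness to the hard parts of real
annotation: indels and split gene models, pseudogene decay, introns with
alternative isoforms, biased codon usage, repeat-induced spurious motif
hits, promoter elements inside repetitive DNA, or EST chimeras. Margins in
real genomes are narrower in every one of those directions.

### Problem sizes used in the shipped checks

The default synthetic genome (150 genes, 40 Mb, ~400 ESTs) runs every
stage in a few minutes on one CPU; the pipeline's bootstrap uses 100
replicates on the 126-taxon NBS alignment. Oracle-equivalence suites use
100–120 random instances per operation; NJ recovery uses 50 random
additive trees with up to 12 taxa; acceptance promoter means use a
dedicated 2,000-promoter batch (SE of the smallest mean ≈ 0.03).

## Numerical and degenerate-input conventions

All genomic coordinates are 1-based inclusive; conversion happens only at
the I/O boundary. Ratios with zero denominators report 0 with a degenerate
flag. NJ Q-matrix ties resolve by the lexicographically smallest leaf-name
pair. Motif windows containing non-standard residues never match; genome
windows containing N never match an element. Alignment scores in the
banded DP are sums of exactly representable binary floats, so the
traceback's transition recomputation is exact. Bootstrap replicates whose
resampled distances saturate contribute no bipartitions, while supports
stay percentages of the full replicate count.

## Known limitations

- The coiled-coil Gaussian calibration is a package-level fit adequate to
  separate heptad repeats from globular/random windows; it is not a
  reproduction of any published program's exact parameter set, and
  borderline predictions (probabilities near 0.9) should not be
  over-interpreted.
- Two-hit seeding can in principle miss a qualifying EST alignment whose
  seeds all fall on distinct distant diagonals (heavily gapped matches);
  at the 90%/100-bp criterion this is vanishingly rare.
- The pipeline's tree stage requires equal-length NBS spans (true for
  generator output); real proteins need an external multiple alignment.
- `reference_similarity` reports stats only for the top-scoring reference;
  a lower-scoring reference could in contrived cases pass the
  coverage/identity filter when the top one fails.
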