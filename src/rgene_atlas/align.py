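"""Pairwise global protein alignment with coverage/identity semantics.

Alignments are global with free terminal gaps (BLOSUM62, gap open 10,
extend 1).  Coverage is the aligned (non-terminal-gap) column span divided
by the length of the longer sequence; identity is matches over aligned
columns excluding terminal gaps.  These are the two statistics every
similarity filter in the pipeline consumes.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=8)
def _aligner(open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    # terminal gaps are free: overhangs are not penalised
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


def pairwise_stats(
    protein_a: str,
    protein_b: str,
    open_gap: float = 10.0,
    extend_gap: float = 1.0,
) -> tuple[float, float]:
    """(coverage, identity) of the best global alignment of two proteins.

    Symmetric in its arguments up to alignment-path ties; both sequences
    must be non-empty.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    aln = _aligner(open_gap, extend_gap).align(protein_a, protein_b)[0]
    return _stats_from_alignment(aln, protein_a, protein_b)


def alignment_score(
    protein_a: str,
    protein_b: str,
    open_gap: float = 10.0,
    extend_gap: float = 1.0,
) -> float:
    """Raw alignment score only (much faster than a full traceback); used
    to rank candidate pairs before computing coverage/identity."""
    return _aligner(open_gap, extend_gap).score(protein_a, protein_b)


def _stats_from_alignment(aln, protein_a: str, protein_b: str) -> tuple[float, float]:
    c = aln.counts()
    trimmed_cols = c.identities + c.mismatches + c.internal_gaps
    if trimmed_cols == 0:
        return 0.0, 0.0
    # aligned (non-terminal-gap) span measured on the longer sequence
    blocks_a, blocks_b = aln.aligned
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    span = span_a if len(protein_a) >= len(protein_b) else span_b
    coverage = span / max(len(protein_a), len(protein_b))
    identity = c.identities / trimmed_cols
    return coverage, identity
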