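"""Regular/nonregular filtering and NBS architecture classes.

A gene is *regular* when its best alignment against a reference R-protein
set covers >=70% of the longer sequence at >=50% identity (both inclusive).
Regular NBS genes are then assigned a letter-code class from their domain
architecture: CNL (CC-NBS-LRR), NL (NBS-LRR), CN (CC-NBS), XN (X-NBS),
plus the atypical CNNL arrangement and a bare-N fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import alignment_score, pairwise_stats
from .domains import DomainArchitecture

REGULAR_MIN_COVERAGE = 0.70
REGULAR_MIN_IDENTITY = 0.50

#: genes failing the >=5-motif NBS rule but retaining at least this many
#: canonical motifs are kept as nonregular rather than discarded
NONREGULAR_MIN_MOTIFS = 3

CLASS_CODES = ("CNL", "NL", "CN", "XN", "CNNL-atypical", "N", "other")


@dataclass
class ClassifiedGene:
    gene_id: str
    regular: bool
    nbs_class: str
    best_hit_coverage: float
    best_hit_identity: float


def is_regular(coverage: float, identity: float) -> bool:
    """Inclusive thresholds: coverage >= 0.70 and identity >= 0.50."""
    if not (0 <= coverage <= 1 and 0 <= identity <= 1):
        raise ValueError("coverage/identity must lie in [0, 1]")
    return coverage >= REGULAR_MIN_COVERAGE and identity >= REGULAR_MIN_IDENTITY


def classify_architecture(arch: DomainArchitecture) -> str:
    """Map an ordered domain list containing NBS to a letter-code class."""
    domains = arch.domains
    n_nbs = domains.count("NBS")
    if n_nbs == 0:
        raise ValueError(f"{arch.gene_id}: architecture without NBS cannot be classified")
    has_cc = "CC" in domains
    has_lrr = "LRR" in domains
    has_x = "X" in domains
    if n_nbs >= 2 and has_cc and has_lrr:
        return "CNNL-atypical"
    if has_cc and has_lrr:
        return "CNL"
    if has_lrr:
        return "NL"
    if has_cc:
        return "CN"
    return "XN" if has_x else "N"


def reference_similarity(
    protein: str, reference_set: dict[str, str] | list[tuple[str, str]]
) -> tuple[float, float]:
    """(coverage, identity) against the best-matching reference.

    References are ranked by raw alignment score (the BLAST best-hit
    convention); coverage and identity are then computed from the full
    alignment against that single reference.  Ties break on reference
    order."""
    items = list(reference_set.items()) if isinstance(reference_set, dict) else list(reference_set)
    if not items:
        raise ValueError("empty reference set")
    best_ref = max(items, key=lambda kv: alignment_score(protein, kv[1]))
    return pairwise_stats(protein, best_ref[1])


def classify_gene(
    gene_id: str,
    protein: str,
    arch: DomainArchitecture,
    reference_set: dict[str, str],
) -> ClassifiedGene:
    """Combine the similarity filter and the motif-based NBS call.

    Regular requires an NBS domain (>=5 canonical motifs in order) *and*
    the coverage/identity filter; genes with an NBS-like motif content
    below the 5-motif rule stay nonregular."""
    cov, ident = reference_similarity(protein, reference_set)
    has_nbs = "NBS" in arch.domains
    regular = has_nbs and is_regular(cov, ident)
    if has_nbs:
        cls = classify_architecture(arch)
    elif len(arch.nbs_motifs_found) >= NONREGULAR_MIN_MOTIFS:
        cls = "N"
    else:
        cls = "other"
    return ClassifiedGene(gene_id, regular, cls, cov, ident)
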