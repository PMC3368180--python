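"""Promoter extraction and cis-regulatory element counting.

The 2-kb region immediately upstream of each gene (strand-aware, truncated
at chromosome ends) is scanned for WBOX (TGACY), CBF (GTCGAC) and GCC
(GCCGCC) consensi with IUPAC matching on both strands.  Overlapping
occurrences are all counted; palindromic consensi are collapsed so the +
and - match at one position count once; windows containing N never match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

from .seqio import Chromosome, GeneModel, reverse_complement

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "N": "ACGT",
}

DEFAULT_UPSTREAM_LENGTH = 2000


@dataclass(frozen=True)
class CisElement:
    name: str
    consensus: str

    def __post_init__(self) -> None:
        for c in self.consensus:
            if c not in IUPAC:
                raise ValueError(f"{self.name}: invalid IUPAC code {c!r}")

    @property
    def is_palindromic(self) -> bool:
        rc = reverse_complement(self.consensus)
        return len(rc) == len(self.consensus) and all(
            set(IUPAC[a]) == set(IUPAC[b]) for a, b in zip(rc, self.consensus)
        )


#: the GCC-box consensus is the canonical ERF-binding GCCGCC
DEFAULT_ELEMENTS = (
    CisElement("WBOX", "TGACY"),
    CisElement("CBF", "GTCGAC"),
    CisElement("GCC", "GCCGCC"),
)


@dataclass
class PromoterProfile:
    gene_id: str
    region: tuple[str, int, int, str]  # chromosome, start, end, strand
    wbox: int
    cbf: int
    gcc: int
    truncated: bool = False


def upstream_region(
    gene: GeneModel,
    genome: dict[str, str] | dict[str, Chromosome],
    length: int = DEFAULT_UPSTREAM_LENGTH,
) -> tuple[str, tuple[str, int, int, str], bool]:
    """The promoter sequence in gene orientation plus its genomic span.

    Plus strand: the ``length`` bases ending immediately before the gene
    start.  Minus strand: the ``length`` bases beginning immediately after
    the gene end, reverse-complemented.  Truncated at chromosome ends."""
    if gene.chromosome not in genome:
        raise KeyError(f"{gene.gene_id}: unknown chromosome {gene.chromosome!r}")
    chrom = genome[gene.chromosome]
    seq = chrom.sequence if isinstance(chrom, Chromosome) else chrom
    if gene.strand == "+":
        start = max(1, gene.start - length)
        end = gene.start - 1
        if end < start:
            return "", (gene.chromosome, gene.start, gene.start - 1, "+"), True
        region = seq[start - 1 : end]
        return region, (gene.chromosome, start, end, "+"), end - start + 1 < length
    start = gene.end + 1
    end = min(len(seq), gene.end + length)
    if end < start:
        return "", (gene.chromosome, gene.end + 1, gene.end, "-"), True
    region = reverse_complement(seq[start - 1 : end])
    return region, (gene.chromosome, start, end, "-"), end - start + 1 < length


@lru_cache(maxsize=64)
def _consensus_regex(consensus: str) -> re.Pattern:
    # N in the text never matches: pattern classes contain only ACGT
    parts = []
    for c in consensus:
        allowed = IUPAC[c]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile(f"(?=({''.join(parts)}))")


def find_occurrences(region: str, element: CisElement, both_strands: bool = True) -> list[tuple[int, str]]:
    """All (1-based position, strand) occurrences of the consensus,
    counting overlaps; palindromic consensi collapse + and - at the same
    position to a single + occurrence."""
    region = region.upper()
    occ = [(m.start() + 1, "+") for m in _consensus_regex(element.consensus).finditer(region)]
    if both_strands and not element.is_palindromic:
        rc = reverse_complement(element.consensus)
        occ += [(m.start() + 1, "-") for m in _consensus_regex(rc).finditer(region)]
    return sorted(occ)


def count_occurrences(region: str, element: CisElement, both_strands: bool = True) -> int:
    """Occurrence count of the consensus in a region (overlaps counted,
    both strands by default, palindromes collapsed)."""
    return len(find_occurrences(region, element, both_strands))


def count_elements(
    gene_id: str,
    region: str,
    region_span: tuple[str, int, int, str] = ("", 0, -1, "+"),
    elements: tuple[CisElement, ...] = DEFAULT_ELEMENTS,
    both_strands: bool = True,
    truncated: bool = False,
) -> PromoterProfile:
    counts = {el.name: count_occurrences(region, el, both_strands) for el in elements}
    return PromoterProfile(
        gene_id=gene_id,
        region=region_span,
        wbox=counts.get("WBOX", 0),
        cbf=counts.get("CBF", 0),
        gcc=counts.get("GCC", 0),
        truncated=truncated,
    )


def promoter_profiles(
    genes: list[GeneModel],
    genome: dict[str, str],
    length: int = DEFAULT_UPSTREAM_LENGTH,
    elements: tuple[CisElement, ...] = DEFAULT_ELEMENTS,
    both_strands: bool = True,
) -> list[PromoterProfile]:
    profiles = []
    for g in genes:
        region, span, truncated = upstream_region(g, genome, length)
        profiles.append(
            count_elements(g.gene_id, region, span, elements, both_strands, truncated)
        )
    return profiles


def promoter_summary(
    profiles: list[PromoterProfile], wbox_at_least: int = 11
) -> dict[str, float]:
    """Mean count per element (2 decimals), % of genes with >= k WBOX and %
    containing all three element types (1 decimal)."""
    if not profiles:
        raise ValueError("promoter_summary requires at least one profile")
    n = len(profiles)
    return {
        "wbox_mean": round(sum(p.wbox for p in profiles) / n, 2),
        "cbf_mean": round(sum(p.cbf for p in profiles) / n, 2),
        "gcc_mean": round(sum(p.gcc for p in profiles) / n, 2),
        f"pct_wbox_ge{wbox_at_least}": round(
            100.0 * sum(p.wbox >= wbox_at_least for p in profiles) / n, 1
        ),
        "pct_all_three": round(
            100.0 * sum(p.wbox > 0 and p.cbf > 0 and p.gcc > 0 for p in profiles) / n, 1
        ),
    }
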