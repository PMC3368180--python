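"""Duplication events, single-linkage gene families, and family statistics.

A pair of genes is a duplication event when their protein alignment covers
>70% of the longer gene at >70% identity (both strict, in contrast to the
inclusive regular-gene filter).  Tandem arrays contribute only adjacent
pairs, so an array of k mutually similar genes yields k-1 events.  Families
are single-linkage connected components of the event graph; singletons are
not families.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import alignment_score, pairwise_stats
from .seqio import GeneModel

EVENT_MIN_COVERAGE = 0.70  # strict >
EVENT_MIN_IDENTITY = 0.70  # strict >
DEFAULT_TANDEM_DISTANCE = 200_000


@dataclass(frozen=True)
class DuplicationEvent:
    gene_a: str
    gene_b: str
    coverage: float
    identity: float
    tandem: bool

    def __post_init__(self) -> None:
        if not (self.coverage > EVENT_MIN_COVERAGE and self.identity > EVENT_MIN_IDENTITY):
            raise ValueError("duplication events require coverage and identity > 0.70")


@dataclass
class GeneFamily:
    family_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a gene family has at least two members")


@dataclass
class DuplicationSummary:
    single_genes: int
    multigene_genes: int
    n_families: int
    max_family_size: int
    avg_members_per_family: float
    multi_to_single_ratio: float
    pct_multigene: float
    degenerate: bool = False  # no families at all


#: score-ratio floor below which a pair cannot reach the >70%/<70% event
#: criterion; pairs under it are reported as (0, 0) without a traceback
PREFILTER_SCORE_RATIO = 0.25


def all_vs_all_stats(
    proteins: dict[str, str], prefilter: bool = True
) -> dict[frozenset[str], tuple[float, float]]:
    """(coverage, identity) for every unordered pair of proteins.

    With ``prefilter`` (default), a fast score-only pass skips the full
    alignment for pairs whose score is far below the duplication
    criterion; the floor is deliberately conservative (a >70%-identity,
    >70%-coverage pair scores well above a quarter of the smaller
    self-score)."""
    ids = sorted(proteins)
    stats: dict[frozenset[str], tuple[float, float]] = {}
    self_score = {a: alignment_score(proteins[a], proteins[a]) for a in ids} if prefilter else {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if prefilter:
                s = alignment_score(proteins[a], proteins[b])
                if s < PREFILTER_SCORE_RATIO * min(self_score[a], self_score[b]):
                    stats[frozenset((a, b))] = (0.0, 0.0)
                    continue
            stats[frozenset((a, b))] = pairwise_stats(proteins[a], proteins[b])
    return stats


def find_events(
    genes: list[GeneModel],
    stats: dict[frozenset[str], tuple[float, float]],
    tandem_distance: int = DEFAULT_TANDEM_DISTANCE,
) -> list[DuplicationEvent]:
    """Qualifying pairs, with the tandem single-count rule applied.

    Among qualifying pairs on the same chromosome with gene starts within
    ``tandem_distance``, only pairs adjacent in the chain of tandem-linked
    genes are retained (one event per neighbouring pair in an array)."""
    loc = {g.gene_id: g for g in genes}
    qualifying: list[tuple[str, str, float, float, bool]] = []
    for pair, (cov, ident) in stats.items():
        if not (cov > EVENT_MIN_COVERAGE and ident > EVENT_MIN_IDENTITY):
            continue
        a, b = sorted(pair)
        ga, gb = loc.get(a), loc.get(b)
        tandem = (
            ga is not None
            and gb is not None
            and ga.chromosome == gb.chromosome
            and abs(ga.start - gb.start) <= tandem_distance
        )
        qualifying.append((a, b, cov, ident, tandem))

    # tandem arrays: keep only pairs adjacent by genomic position among the
    # genes of each mutually-linked tandem component
    tandem_pairs = {(a, b) for a, b, _c, _i, t in qualifying if t}
    adj: dict[str, set[str]] = {}
    for a, b in tandem_pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    keep_tandem: set[tuple[str, str]] = set()
    seen: set[str] = set()
    for start_node in sorted(adj):
        if start_node in seen:
            continue
        component = []
        stack = [start_node]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            component.append(node)
            stack.extend(adj[node] - seen)
        component.sort(key=lambda gid: (loc[gid].chromosome, loc[gid].start, gid))
        for x, y in zip(component, component[1:]):
            pair = tuple(sorted((x, y)))
            if pair in tandem_pairs:
                keep_tandem.add(pair)

    events = []
    for a, b, cov, ident, tandem in sorted(qualifying):
        if tandem and (a, b) not in keep_tandem:
            continue
        events.append(DuplicationEvent(a, b, cov, ident, tandem))
    return events


def build_families(events: list[DuplicationEvent]) -> list[GeneFamily]:
    """Single-linkage closure of the event graph; components of size >= 2
    become families, numbered fam001.. by smallest member id."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ev in events:
        for g in (ev.gene_a, ev.gene_b):
            parent.setdefault(g, g)
        ra, rb = find(ev.gene_a), find(ev.gene_b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for g in parent:
        groups.setdefault(find(g), set()).add(g)
    families = sorted(groups.values(), key=lambda s: min(s))
    return [
        GeneFamily(f"fam{i:03d}", frozenset(members))
        for i, members in enumerate(families, 1)
        if len(members) >= 2
    ]


def summarize(families: list[GeneFamily], all_gene_ids: set[str] | list[str]) -> DuplicationSummary:
    """Family statistics with the printed-table formatting conventions:
    percentages to 1 decimal, ratios to 2 decimals."""
    all_ids = set(all_gene_ids)
    multigene = set()
    for fam in families:
        if not fam.members <= all_ids:
            raise ValueError("family members must be a subset of all_gene_ids")
        if multigene & fam.members:
            raise ValueError("families must be disjoint")
        multigene |= fam.members
    return summary_from_counts(
        multigene_genes=len(multigene),
        n_families=len(families),
        single_genes=len(all_ids) - len(multigene),
        max_family_size=max((len(f.members) for f in families), default=0),
    )


def summary_from_counts(
    multigene_genes: int,
    n_families: int,
    single_genes: int,
    max_family_size: int = 0,
) -> DuplicationSummary:
    """The per-genome duplication statistics from their raw counts (usable
    directly on published per-genome count tables)."""
    total = multigene_genes + single_genes
    degenerate = n_families == 0
    avg = 0.0 if degenerate else round(multigene_genes / n_families, 2)
    ratio = 0.0 if single_genes == 0 else round(multigene_genes / single_genes, 2)
    pct = 0.0 if total == 0 else round(100.0 * multigene_genes / total, 1)
    return DuplicationSummary(
        single_genes=single_genes,
        multigene_genes=multigene_genes,
        n_families=n_families,
        max_family_size=max_family_size,
        avg_members_per_family=avg,
        multi_to_single_ratio=ratio,
        pct_multigene=pct,
        degenerate=degenerate,
    )


def segmental_duplicates(
    families: list[GeneFamily], genes: list[GeneModel]
) -> list[tuple[str, str]]:
    """Family-member pairs on different chromosomes: candidate segmental
    (as opposed to tandem) duplications."""
    chrom = {g.gene_id: g.chromosome for g in genes}
    pairs = []
    for fam in families:
        members = sorted(fam.members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if chrom[a] != chrom[b]:
                    pairs.append((a, b))
    return sorted(pairs)
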