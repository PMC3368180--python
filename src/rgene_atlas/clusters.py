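"""Sliding-window genomic gene clusters.

A gene belongs to a cluster when it lies in at least one window of width
``window_size`` (gene position = start coordinate, start-to-start span
measured inclusively) containing ``min_genes`` or more genes; overlapping
qualifying windows on a chromosome merge into maximal clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqio import GeneModel

DEFAULT_WINDOW = 200_000
DEFAULT_MIN_GENES = 4
SUPERCLUSTER_WINDOW = 430_000
SUPERCLUSTER_MIN_GENES = 8


@dataclass
class GeneCluster:
    cluster_id: str
    chromosome: str
    members: list[str]  # ordered by start
    span_start: int
    span_end: int
    window_size: int


def _qualifying_intervals(starts: list[int], window_size: int, min_genes: int) -> list[tuple[int, int]]:
    """Maximal qualifying windows as index intervals into the sorted start
    list, merged wherever two windows share a gene.

    Any window with >= min_genes genes can be slid left until its left edge
    sits on a gene without losing genes, so windows anchored at each gene
    are exhaustive."""
    n = len(starts)
    intervals: list[tuple[int, int]] = []
    j = 0
    for i in range(n):
        if j < i:
            j = i
        while j + 1 < n and starts[j + 1] - starts[i] <= window_size:
            j += 1
        if j - i + 1 >= min_genes:
            intervals.append((i, j))
    merged: list[list[int]] = []
    for i, j in intervals:
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    return [(i, j) for i, j in merged]


def find_clusters(
    genes: list[GeneModel],
    window_size: int = DEFAULT_WINDOW,
    min_genes: int = DEFAULT_MIN_GENES,
) -> list[GeneCluster]:
    """Maximal clusters per chromosome; output is independent of the input
    gene order."""
    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        starts = [g.start for g in gs]
        k = 0
        for i, j in _qualifying_intervals(starts, window_size, min_genes):
            clusters.append(_make_cluster(gs, list(range(i, j + 1)), chrom, window_size, k))
            k += 1
    return clusters


def _make_cluster(
    gs: list[GeneModel], idx: list[int], chrom: str, window_size: int, k: int
) -> GeneCluster:
    members = [gs[i] for i in idx]
    return GeneCluster(
        cluster_id=f"{chrom}.c{k + 1}",
        chromosome=chrom,
        members=[g.gene_id for g in members],
        span_start=min(g.start for g in members),
        span_end=max(g.end for g in members),
        window_size=window_size,
    )


def cluster_fraction(
    genes: list[GeneModel],
    window_size: int = DEFAULT_WINDOW,
    min_genes: int = DEFAULT_MIN_GENES,
) -> int:
    """Percentage of genes lying in any qualifying cluster, rounded to the
    nearest integer."""
    if not genes:
        return 0
    clustered = sum(len(c.members) for c in find_clusters(genes, window_size, min_genes))
    return round(100.0 * clustered / len(genes))


def superclusters(
    genes: list[GeneModel],
    window_size: int = SUPERCLUSTER_WINDOW,
    min_genes: int = SUPERCLUSTER_MIN_GENES,
) -> list[GeneCluster]:
    """The relaxed-window variant used to find large extended clusters."""
    return find_clusters(genes, window_size, min_genes)


def chromosome_map(genes: list[GeneModel], clusters: list[GeneCluster]) -> pd.DataFrame:
    """Per-gene table of chromosome/position/cluster membership (one row
    per gene)."""
    cluster_of = {}
    for c in clusters:
        for gid in c.members:
            cluster_of[gid] = c.cluster_id
    rows = [
        {
            "gene_id": g.gene_id,
            "chromosome": g.chromosome,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "cluster_id": cluster_of.get(g.gene_id, ""),
        }
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand", "cluster_id"])


def plot_chromosome_map(genes: list[GeneModel], clusters: list[GeneCluster], path: str) -> None:
    """Scaled ideogram of gene positions per chromosome (megabase axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = chromosome_map(genes, clusters)
    chroms = sorted(table["chromosome"].unique())
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 1.6 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = table[table["chromosome"] == chrom]
        clustered = sub["cluster_id"] != ""
        ax.vlines(sub.loc[~clustered, "start"] / 1e6, 0, 1, color="grey", lw=0.8)
        ax.vlines(sub.loc[clustered, "start"] / 1e6, 0, 1, color="crimson", lw=1.2)
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
        ax.set_yticks([])
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
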