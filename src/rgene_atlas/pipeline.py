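"""End-to-end orchestration: scan -> classify -> duplication -> clustering ->
promoters -> tree -> expression, with consolidated per-gene reporting.

Every stage parameter lives once in :class:`PipelineConfig` and is written
back out with the run (resolved-config.yaml) for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clusters as clustering
from . import duplication, expression, phylogeny, promoters
from .classify import ClassifiedGene, classify_gene
from .domains import (
    DEFAULT_CC_THRESHOLD,
    DEFAULT_MAX_MISMATCH_FRACTION,
    DomainArchitecture,
    analyze_protein,
)
from .seqio import GeneModel, attach_sequences, read_fasta, read_gff3, write_newick


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    genome_fa: str = ""
    gff3: str = ""
    proteins_fa: str = ""
    ests_fa: str = ""
    refs_fa: str = ""
    outdir: str = "rgene_atlas_out"
    # domain scan
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION
    min_nbs_motifs: int = 5
    cc_threshold: float = DEFAULT_CC_THRESHOLD
    # duplication
    tandem_distance: int = duplication.DEFAULT_TANDEM_DISTANCE
    # clustering
    cluster_window: int = clustering.DEFAULT_WINDOW
    cluster_min_genes: int = clustering.DEFAULT_MIN_GENES
    supercluster_window: int = clustering.SUPERCLUSTER_WINDOW
    supercluster_min_genes: int = clustering.SUPERCLUSTER_MIN_GENES
    # promoters
    promoter_length: int = promoters.DEFAULT_UPSTREAM_LENGTH
    promoter_both_strands: bool = True
    wbox_at_least: int = 11
    # phylogeny
    tree_distance: str = "poisson"
    bootstrap_reps: int = 100
    seed: int = 0
    # expression
    est_min_identity: float = expression.DEFAULT_MIN_IDENTITY
    est_min_overlap: int = expression.DEFAULT_MIN_OVERLAP
    est_best_hit: bool = False


#: provenance of every default: a stated method parameter or a documented
#: design choice of this package (see docs/methods.md)
PARAM_PROVENANCE = {
    "genome_fa": "input path",
    "gff3": "input path",
    "proteins_fa": "input path",
    "ests_fa": "input path",
    "refs_fa": "input path",
    "outdir": "output path",
    "max_mismatch_fraction": "design choice: motif degeneracy budget (methods note)",
    "min_nbs_motifs": "method: at least five of the eight canonical NBS motifs",
    "cc_threshold": "design choice: coiled-coil probability cutoff (methods note)",
    "tandem_distance": "design choice: tandem linkage distance = cluster window",
    "cluster_window": "method: 200-kb sliding window cluster definition",
    "cluster_min_genes": "method: four or more genes per cluster",
    "supercluster_window": "method: relaxed 430-kb window",
    "supercluster_min_genes": "design choice: supercluster size floor (methods note)",
    "promoter_length": "method: 2-kb upstream promoter window",
    "promoter_both_strands": "design choice: both-strand element counting",
    "wbox_at_least": "method: share of genes with at least 11 WBOX elements",
    "tree_distance": "design choice: Poisson correction for protein alignments",
    "bootstrap_reps": "design choice: bootstrap replicates (methods note)",
    "seed": "reproducibility",
    "est_min_identity": "method: 90% identity for significant EST matches",
    "est_min_overlap": "design choice: minimum EST alignment length (methods note)",
    "est_best_hit": "design choice: ESTs count for every passing gene by default",
}


@dataclass
class PipelineResult:
    config: PipelineConfig
    genes: list[GeneModel]
    architectures: dict[str, DomainArchitecture]
    classified: dict[str, ClassifiedGene]
    regular_ids: list[str]
    events: list[duplication.DuplicationEvent]
    families: list[duplication.GeneFamily]
    dup_summary: duplication.DuplicationSummary
    segmental_pairs: list[tuple[str, str]]
    clusters: list[clustering.GeneCluster]
    superclusters: list[clustering.GeneCluster]
    promoter_profiles: list[promoters.PromoterProfile]
    promoter_summary: dict[str, float]
    tree: phylogeny.Node | None
    est_supports: list[expression.ESTSupport]
    est_summary: dict[str, float]
    log: list[str] = field(default_factory=list)

    def gene_report(self) -> pd.DataFrame:
        fam_of = {}
        for fam in self.families:
            for g in fam.members:
                fam_of[g] = fam.family_id
        clu_of = {}
        for c in self.clusters:
            for g in c.members:
                clu_of[g] = c.cluster_id
        prom = {p.gene_id: p for p in self.promoter_profiles}
        est = {s.gene_id: s.est_count for s in self.est_supports}
        rows = []
        for g in sorted(self.genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            cl = self.classified.get(g.gene_id)
            p = prom.get(g.gene_id)
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chromosome": g.chromosome,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "nbs_class": cl.nbs_class if cl else "",
                    "regular": bool(cl.regular) if cl else False,
                    "family_id": fam_of.get(g.gene_id, ""),
                    "cluster_id": clu_of.get(g.gene_id, ""),
                    "wbox": p.wbox if p else "",
                    "cbf": p.cbf if p else "",
                    "gcc": p.gcc if p else "",
                    "est_count": est.get(g.gene_id, ""),
                }
            )
        return pd.DataFrame(rows)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for gid in self.regular_ids:
            cls = self.classified[gid].nbs_class
            counts[cls] = counts.get(cls, 0) + 1
        return counts


def run(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write the report directory."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    genome = dict(stage("read_genome", read_fasta, cfg.genome_fa)) if cfg.genome_fa else {}
    genes = stage("read_gff3", read_gff3, cfg.gff3)
    proteins = dict(stage("read_proteins", read_fasta, cfg.proteins_fa))
    ests = stage("read_ests", read_fasta, cfg.ests_fa) if cfg.ests_fa else []
    refs = dict(stage("read_refs", read_fasta, cfg.refs_fa))
    if genome:
        attach_sequences(genes, genome=genome, proteins=proteins)
    log.append(f"inputs: {len(genes)} genes, {len(proteins)} proteins, {len(ests)} ESTs, {len(refs)} references")

    # domain scan
    archs: dict[str, DomainArchitecture] = {}
    for g in genes:
        prot = proteins.get(g.gene_id)
        if prot is None:
            raise PipelineError(f"stage 'scan' failed: no protein for {g.gene_id}")
        archs[g.gene_id] = analyze_protein(
            g.gene_id, prot, cfg.max_mismatch_fraction, cfg.min_nbs_motifs, cfg.cc_threshold
        )
    with_nbs = sum("NBS" in a.domains for a in archs.values())
    log.append(f"scan: {with_nbs}/{len(archs)} proteins carry an NBS domain")

    # classification
    classified = {
        gid: stage("classify", classify_gene, gid, proteins[gid], archs[gid], refs)
        for gid in sorted(archs)
    }
    regular_ids = [gid for gid, c in classified.items() if c.regular]
    log.append(f"classify: {len(regular_ids)} regular genes survived the similarity filter")

    regular_genes = [g for g in genes if g.gene_id in set(regular_ids)]
    regular_prots = {gid: proteins[gid] for gid in regular_ids}

    # duplication
    stats = stage("duplication", duplication.all_vs_all_stats, regular_prots)
    events = stage("duplication", duplication.find_events, regular_genes, stats, cfg.tandem_distance)
    families = stage("duplication", duplication.build_families, events)
    dup_summary = stage("duplication", duplication.summarize, families, set(regular_ids))
    segmental = stage("duplication", duplication.segmental_duplicates, families, regular_genes)
    log.append(
        f"duplication: {len(events)} events, {dup_summary.n_families} families, "
        f"{dup_summary.multigene_genes} multigene genes, {len(segmental)} segmental pairs"
    )

    # clustering
    clus = stage("clustering", clustering.find_clusters, regular_genes, cfg.cluster_window, cfg.cluster_min_genes)
    supers = stage(
        "clustering", clustering.superclusters, regular_genes, cfg.supercluster_window, cfg.supercluster_min_genes
    )
    log.append(f"clustering: {len(clus)} clusters, {len(supers)} superclusters")

    # promoters
    profiles = []
    prom_summary: dict[str, float] = {}
    if genome:
        profiles = stage(
            "promoters",
            promoters.promoter_profiles,
            regular_genes,
            genome,
            cfg.promoter_length,
            promoters.DEFAULT_ELEMENTS,
            cfg.promoter_both_strands,
        )
        prom_summary = promoters.promoter_summary(profiles, cfg.wbox_at_least)
        log.append(f"promoters: {len(profiles)} regions scanned")

    # phylogeny on the detected NBS spans (equal-length by construction for
    # indel-free inputs; otherwise a precomputed alignment must be supplied
    # through the tree subcommand)
    tree = None
    if len(regular_ids) >= 3:
        spans = {}
        for gid in regular_ids:
            span = archs[gid].nbs_span
            if span is None:
                raise PipelineError(f"stage 'tree' failed: no NBS span for regular gene {gid}")
            spans[gid] = proteins[gid][span[0] - 1 : span[1]]
        lengths = {len(s) for s in spans.values()}
        if len(lengths) != 1:
            raise PipelineError(
                "stage 'tree' failed: NBS spans differ in length; supply an alignment via the tree subcommand"
            )
        alignment = [(gid, spans[gid]) for gid in sorted(spans)]
        trimmed, _map = stage("tree", phylogeny.gblocks_lite, alignment)
        tree = stage(
            "tree", phylogeny.bootstrap, trimmed, cfg.bootstrap_reps, cfg.seed, cfg.tree_distance
        )
        log.append(f"tree: {len(alignment)} taxa, {len(trimmed[0][1])} columns retained")

    # expression
    supports: list[expression.ESTSupport] = []
    est_summary: dict[str, float] = {}
    if ests:
        cds = {g.gene_id: g.cds_sequence for g in regular_genes}
        if any(not s for s in cds.values()):
            raise PipelineError("stage 'expression' failed: missing CDS sequences (genome required)")
        supports, est_summary = stage(
            "expression",
            expression.support_table,
            cds,
            ests,
            cfg.est_min_identity,
            cfg.est_min_overlap,
            cfg.est_best_hit,
        )
        log.append(
            f"expression: {est_summary['n_unsupported']}/{est_summary['n_genes']} regular genes without EST support"
        )

    result = PipelineResult(
        config=cfg,
        genes=genes,
        architectures=archs,
        classified=classified,
        regular_ids=regular_ids,
        events=events,
        families=families,
        dup_summary=dup_summary,
        segmental_pairs=segmental,
        clusters=clus,
        superclusters=supers,
        promoter_profiles=profiles,
        promoter_summary=prom_summary,
        tree=tree,
        est_supports=supports,
        est_summary=est_summary,
        log=log,
    )
    _write_reports(result, out)
    return result


def _write_reports(res: PipelineResult, out: Path) -> None:
    cfg = res.config
    res.gene_report().to_csv(out / "genes.tsv", sep="\t", index=False)

    counts = res.class_counts()
    nonregular = len(res.genes) - len(res.regular_ids)
    table1 = pd.DataFrame(
        [
            {"predicted_domain": "CC-NBS-LRR", "letter_code": "CNL", "n_genes": counts.get("CNL", 0)},
            {"predicted_domain": "NBS-LRR", "letter_code": "NL", "n_genes": counts.get("NL", 0)},
            {"predicted_domain": "CC-NBS", "letter_code": "CN", "n_genes": counts.get("CN", 0)},
            {"predicted_domain": "X-NBS", "letter_code": "XN", "n_genes": counts.get("XN", 0)},
            {"predicted_domain": "other", "letter_code": "other",
             "n_genes": len(res.regular_ids) - sum(counts.get(k, 0) for k in ("CNL", "NL", "CN", "XN"))},
            {"predicted_domain": "Total regular NBS genes", "letter_code": "", "n_genes": len(res.regular_ids)},
            {"predicted_domain": "Total nonregular or other genes", "letter_code": "", "n_genes": nonregular},
            {"predicted_domain": "Total genes", "letter_code": "", "n_genes": len(res.genes)},
        ]
    )
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)

    s = res.dup_summary
    table3 = pd.DataFrame(
        [
            ("Single-genes", s.single_genes),
            ("Multigenes", s.multigene_genes),
            ("Number of family members", s.n_families),
            ("Maximal family members", s.max_family_size),
            ("Average members per family", s.avg_members_per_family),
            ("Multigenes/single-gene families", s.multi_to_single_ratio),
            ("Percentage of multigene families", s.pct_multigene),
        ],
        columns=["statistic", "value"],
    )
    table3.to_csv(out / "table3.tsv", sep="\t", index=False)

    fam_rows = [
        {"family_id": f.family_id, "size": len(f.members), "members": ",".join(sorted(f.members))}
        for f in res.families
    ]
    pd.DataFrame(fam_rows, columns=["family_id", "size", "members"]).to_csv(
        out / "families.tsv", sep="\t", index=False
    )

    clu_rows = [
        {
            "cluster_id": c.cluster_id,
            "chromosome": c.chromosome,
            "n_genes": len(c.members),
            "span_start": c.span_start,
            "span_end": c.span_end,
            "members": ",".join(c.members),
        }
        for c in res.clusters
    ]
    pd.DataFrame(
        clu_rows, columns=["cluster_id", "chromosome", "n_genes", "span_start", "span_end", "members"]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)

    prom_rows = [
        {
            "gene_id": p.gene_id,
            "chromosome": p.region[0],
            "region_start": p.region[1],
            "region_end": p.region[2],
            "strand": p.region[3],
            "wbox": p.wbox,
            "cbf": p.cbf,
            "gcc": p.gcc,
            "truncated": p.truncated,
        }
        for p in res.promoter_profiles
    ]
    pd.DataFrame(
        prom_rows,
        columns=["gene_id", "chromosome", "region_start", "region_end", "strand", "wbox", "cbf", "gcc", "truncated"],
    ).to_csv(out / "promoters.tsv", sep="\t", index=False)

    est_rows = [{"gene_id": s.gene_id, "est_count": s.est_count, "supported": s.supported} for s in res.est_supports]
    pd.DataFrame(est_rows, columns=["gene_id", "est_count", "supported"]).to_csv(
        out / "est_support.tsv", sep="\t", index=False
    )

    if res.tree is not None:
        write_newick(res.tree, out / "tree.nwk")

    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(res.log) + "\n")
    with open(out / "resolved-config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def predicted_label(res: PipelineResult, gene_id: str) -> str:
    """Map pipeline calls onto generator truth vocabulary: a regular gene
    keeps its class; an NBS-motif-bearing gene failing the rules is
    'nonregular'; anything else is 'background'."""
    cl = res.classified[gene_id]
    if cl.regular:
        return cl.nbs_class
    arch = res.architectures[gene_id]
    if "NBS" in arch.domains or len(arch.nbs_motifs_found) >= 3:
        return "nonregular"
    return "background"


def compare_to_truth(res: PipelineResult, truth) -> pd.DataFrame:
    """Per-stage precision/recall/exact-match metrics against planted truth."""
    gene_ids = sorted(g.gene_id for g in res.genes)
    if set(gene_ids) != set(truth.class_labels):
        raise ValueError("report and truth cover different gene sets")

    # class accuracy over all genes
    correct = sum(predicted_label(res, gid) == truth.class_labels[gid] for gid in gene_ids)
    rows = [("class_accuracy", correct / len(gene_ids))]

    # family membership: pairwise co-membership precision/recall
    def pairs(groups) -> set[frozenset[str]]:
        out = set()
        for members in groups:
            ms = sorted(members)
            for i, a in enumerate(ms):
                for b in ms[i + 1 :]:
                    out.add(frozenset((a, b)))
        return out

    true_pairs = pairs(truth.families)
    pred_pairs = pairs(f.members for f in res.families)
    rows.append(("family_pair_precision", _safe_ratio(len(true_pairs & pred_pairs), len(pred_pairs))))
    rows.append(("family_pair_recall", _safe_ratio(len(true_pairs & pred_pairs), len(true_pairs))))

    # cluster membership
    true_clustered = set().union(*(m for _c, m in truth.clusters)) if truth.clusters else set()
    pred_clustered = set().union(*(set(c.members) for c in res.clusters)) if res.clusters else set()
    rows.append(("cluster_gene_precision", _safe_ratio(len(true_clustered & pred_clustered), len(pred_clustered))))
    rows.append(("cluster_gene_recall", _safe_ratio(len(true_clustered & pred_clustered), len(true_clustered))))

    # promoter element counts: exact-match rate over scanned genes
    if res.promoter_profiles:
        exact = sum(
            (p.wbox, p.cbf, p.gcc) == tuple(truth.promoter_counts[p.gene_id])
            for p in res.promoter_profiles
        )
        rows.append(("promoter_exact_rate", exact / len(res.promoter_profiles)))

    # EST counts: exact-match rate over supported-tested genes
    if res.est_supports:
        exact = sum(s.est_count == truth.est_counts.get(s.gene_id, -1) for s in res.est_supports)
        rows.append(("est_exact_rate", exact / len(res.est_supports)))

    return pd.DataFrame(rows, columns=["metric", "value"])


def _safe_ratio(num: int, den: int) -> float:
    return 1.0 if den == 0 else num / den
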