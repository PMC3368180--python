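"""Synthetic genome generator with planted, machine-readable ground truth.

The generator emulates a small diploid-like genome whose resistance-gene
complement has the statistical structure the analysis assumes: genes with
planted CC/NBS/LRR architectures built from the packaged consensus motifs,
multigene families derived from common ancestors by point substitution,
genomic clusters of four or more genes within a 200-kb window, promoters
carrying Poisson-distributed WBOX/CBF/GCC element counts on screened
background, and an EST library with controlled per-gene coverage and
divergence.

Recovery of every planted feature by the analysis modules is guaranteed by
construction: random segments (linkers, N-termini, promoter background)
are rejection-sampled until they create no spurious motif, coiled-coil or
cis-element hits, and family point mutations never touch planted motif
positions ("collision screening").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import domains
from .domains import (
    CANONICAL_LABELS,
    DomainArchitecture,
    analyze_protein,
    load_motifs,
)
from .promoters import DEFAULT_ELEMENTS, CisElement, count_occurrences, find_occurrences
from .seqio import GeneModel, reverse_complement, write_fasta, write_gff3

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

#: representative motif id per canonical NBS label, in canonical order
CANONICAL_MOTIF_IDS = {
    "P-loop": 2,
    "RNBS-A": 14,
    "Kinase-2": 7,
    "RNBS-B": 10,
    "RNBS-C": 19,
    "GLPL": 3,
    "RNBS-D": 1,
    "MHDV": 6,
}

#: the coiled-coil heptad planted at CC-type N-termini (strong a/d core)
CC_HEPTAD = "LEALEAK"
CC_REPEATS = 4

GENETIC_CODE = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}
STOP_CODONS = ("TAA", "TGA", "TAG")


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic genome.

    Defaults mirror the composition the analysis is calibrated against:
    126 regular genes in proportions 102 CNL : 12 NL : 11 CN : 1 XN, 20
    multigene families (49 genes, largest 7), 11 genomic clusters of >=4
    genes within 200 kb on three of five chromosomes, promoter element
    means (17.10, 3.36, 2.01) and 8% of regular genes without EST support.
    """

    n_chromosomes: int = 5
    chromosome_length: int = 8_000_000
    class_counts: dict = field(
        default_factory=lambda: {"CNL": 102, "NL": 12, "CN": 11, "XN": 1}
    )
    quota_mode: bool = True
    n_nonregular: int = 14
    n_background: int = 10
    family_sizes: tuple = (7, 4, 3, 3) + (2,) * 16
    n_segmental_families: int = 2
    cluster_sizes: tuple = (7, 7, 4, 4, 4, 4, 4, 4, 4, 4, 4)
    cluster_window: int = 200_000
    cluster_chromosomes: tuple | None = None  # default: chr1, chr2, chr4
    gene_spacing: int = 210_000
    promoter_means: tuple = (17.10, 3.36, 2.01)
    promoter_length: int = 2000
    est_mean_coverage: float = 3.0
    est_divergence: float = 0.02
    est_unsupported_fraction: float = 0.08
    member_divergence: float = 0.15
    motif_divergence: float = 0.20
    seed: int = 42

    @property
    def n_regular(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth for one generated genome."""

    architectures: dict[str, list[str]]
    class_labels: dict[str, str]
    families: list[frozenset[str]]
    clusters: list[tuple[str, frozenset[str]]]
    promoter_counts: dict[str, tuple[int, int, int]]
    est_counts: dict[str, int]
    ancestor_of: dict[str, str]
    segmental_pairs: list[tuple[str, str]]


@dataclass
class SyntheticGenome:
    config: GeneratorConfig
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    proteins: dict[str, str]
    cds: dict[str, str]
    promoters: dict[str, str]
    ests: list[tuple[str, str]]
    refs: dict[str, str]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(sorted(self.chromosomes.items()), outdir / "genome.fa", width=80)
        write_gff3(self.genes, outdir / "genes.gff3")
        write_fasta(sorted(self.proteins.items()), outdir / "proteins.fa")
        write_fasta(sorted(self.cds.items()), outdir / "cds.fa")
        write_fasta(self.ests, outdir / "ests.fa")
        write_fasta(sorted(self.refs.items()), outdir / "refs.fa")
        truth_report(self.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)


class GenerationError(RuntimeError):
    pass


# --- protein construction -------------------------------------------------


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA), size=n))


def mutate_protein(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: set[int] | None = None,
) -> str:
    """Point substitutions at the given per-site rate (no indels), skipping
    0-based ``protected`` positions.  Substituted residues always change."""
    out = list(seq)
    for i in range(len(out)):
        if protected and i in protected:
            continue
        if rng.random() < rate:
            choices = AA.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _mutate_motif(consensus: str, core_start: int, core_len: int, rate: float, rng) -> str:
    """Diverge a planted motif instance without breaking detectability:
    only non-core positions mutate, within the scanner's mismatch budget."""
    n = len(consensus)
    non_core = [i for i in range(n) if not (core_start <= i < core_start + core_len)]
    k = int(np.floor(rate * n))
    k = min(k, len(non_core))
    picks = rng.choice(len(non_core), size=k, replace=False) if k else []
    out = list(consensus)
    for p in picks:
        i = non_core[int(p)]
        choices = AA.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


@dataclass
class _Blueprint:
    """Positions (0-based) of the planted segments of one ancestor protein."""

    protein: str
    protected: set[int]
    expected_domains: list[str]
    expected_labels: set[str]
    lrr_count: int
    nbs_span: tuple[int, int]  # 1-based


class _Architect:
    """Builds ancestor proteins for each architecture class using one fixed
    genome-wide NBS template (motif order and inter-motif linker lengths),
    so detected NBS spans are equal-length across regular genes."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        self.motifs = {m.motif_id: m for m in load_motifs()}
        # fixed inter-motif linker lengths (7 linkers)
        self.nbs_linkers = [int(x) for x in rng.integers(8, 17, size=7)]
        self.pre_nbs_linker = 10
        self.post_nbs_linker = 8

    def _nbs_block(self, rng, order: list[str] | None = None, subset: list[str] | None = None) -> tuple[str, list[tuple[int, int]]]:
        """The NBS region: canonical motifs (per-ancestor mutated copies)
        separated by random linkers of fixed length.  Returns the block and
        the (offset, length) spans of the motif instances within it."""
        labels = order or list(CANONICAL_LABELS)
        if subset is not None:
            labels = [l for l in labels if l in subset]
        parts = []
        motif_spans: list[tuple[int, int]] = []
        pos = 0
        for k, label in enumerate(labels):
            motif = self.motifs[CANONICAL_MOTIF_IDS[label]]
            inst = _mutate_motif(
                motif.consensus,
                motif.core_start,
                len(motif.bold_core),
                self.config.motif_divergence,
                rng,
            )
            parts.append(inst)
            motif_spans.append((pos, len(inst)))
            pos += len(inst)
            if k < len(labels) - 1:
                ln = self.nbs_linkers[k % len(self.nbs_linkers)]
                parts.append(random_protein(rng, ln))
                pos += ln
        return "".join(parts), motif_spans

    def _lrr_region(self, rng, repeats: int) -> str:
        out = []
        for _ in range(repeats):
            unit = []
            for j, c in enumerate(domains.LRR_CONSENSUS):
                if c == "L":
                    unit.append("LIV"[rng.integers(3)])
                elif c == "N":
                    unit.append("NTS"[rng.integers(3)])
                else:
                    unit.append(AA[rng.integers(len(AA))])
            out.append("".join(unit))
        return "".join(out)

    def build(self, cls: str, rng: np.random.Generator, max_tries: int = 60) -> _Blueprint:
        for _ in range(max_tries):
            bp = self._assemble(cls, rng)
            if bp is not None and self._verify(bp):
                return bp
        raise GenerationError(f"could not build a clean {cls} ancestor")

    def _assemble(self, cls: str, rng) -> _Blueprint | None:
        cfg = self.config
        motif8 = self.motifs[8]
        pieces: list[str] = []
        protected: set[int] = set()
        pos = 0

        def add(segment: str, protect: bool) -> None:
            nonlocal pos
            pieces.append(segment)
            if protect:
                protected.update(range(pos, pos + len(segment)))
            pos += len(segment)

        if cls in ("CNL", "CN"):
            add(CC_HEPTAD * CC_REPEATS, True)
            add(_mutate_motif(motif8.consensus, motif8.consensus.index("QVRD"), 4, cfg.motif_divergence, rng), True)
        elif cls in ("NL", "XN", "nonregular"):
            add(random_protein(rng, 40), False)
        add(random_protein(rng, self.pre_nbs_linker), False)

        nbs_start = pos + 1
        if cls == "nonregular":
            if rng.random() < 0.5:
                # too few motifs: four canonical labels, canonical order
                block, spans = self._nbs_block(rng, subset=["P-loop", "Kinase-2", "GLPL", "MHDV"])
            else:
                # all eight motifs in a non-canonical order
                order = list(CANONICAL_LABELS)
                while True:
                    rng.shuffle(order)
                    if order != list(CANONICAL_LABELS):
                        break
                block, spans = self._nbs_block(rng, order=order)
        else:
            block, spans = self._nbs_block(rng)
        # motif instances inside the block are protected, linkers are not
        block_start = pos
        add(block, False)
        for off, ln in spans:
            protected.update(range(block_start + off, block_start + off + ln))
        nbs_end = pos

        lrr_count = 0
        if cls in ("CNL", "NL"):
            add(random_protein(rng, self.post_nbs_linker), False)
            lrr_count = int(rng.integers(2, 5))
            add(self._lrr_region(rng, lrr_count), True)
        add(random_protein(rng, 12), False)

        expected = {
            "CNL": ["CC", "NBS", "LRR"],
            "NL": ["X", "NBS", "LRR"],
            "CN": ["CC", "NBS"],
            "XN": ["X", "NBS"],
            "nonregular": None,
        }[cls]
        labels = set(CANONICAL_LABELS) if cls != "nonregular" else None
        return _Blueprint(
            protein="".join(pieces),
            protected=protected,
            expected_domains=expected,
            expected_labels=labels,
            lrr_count=lrr_count,
            nbs_span=(nbs_start, nbs_end),
        )

    def _verify(self, bp: _Blueprint) -> bool:
        return _architecture_ok(bp, analyze_protein("x", bp.protein))


def _architecture_ok(bp: _Blueprint, arch: DomainArchitecture) -> bool:
    if bp.expected_domains is None:  # nonregular: NBS must NOT be called
        return "NBS" not in arch.domains and len(arch.nbs_motifs_found) >= 3
    if arch.domains != bp.expected_domains:
        return False
    if arch.nbs_motifs_found != bp.expected_labels:
        return False
    if arch.nbs_span != bp.nbs_span:
        return False
    if "LRR" in bp.expected_domains and arch.lrr_repeat_count != bp.lrr_count:
        return False
    return True


# --- promoter construction ------------------------------------------------


def generate_promoter(
    rng: np.random.Generator,
    means: tuple[float, float, float],
    length: int = 2000,
    elements: tuple[CisElement, ...] = DEFAULT_ELEMENTS,
    max_tries: int = 50,
) -> tuple[str, tuple[int, int, int]]:
    """A promoter of the given length carrying exactly Poisson(lambda)
    planted occurrences of each element and none elsewhere.

    Background is screened so that no consensus matches on either strand,
    elements are planted at non-overlapping positions, and the final
    region is re-scanned; planting is retried until counts are exact."""
    counts = tuple(int(rng.poisson(m)) for m in means)
    for _ in range(max_tries):
        region = _screened_background(rng, length, elements)
        placed = _plant_elements(rng, region, counts, elements)
        if placed is None:
            continue
        realized = tuple(count_occurrences(placed, el) for el in elements)
        if realized == counts:
            return placed, counts
    raise GenerationError("could not plant promoter elements cleanly")


def _screened_background(rng, length, elements, max_iter: int = 400) -> str:
    region = list("".join(rng.choice(list(NT), size=length)))
    for _ in range(max_iter):
        occ = []
        text = "".join(region)
        for el in elements:
            occ.extend((p, len(el.consensus)) for p, _s in find_occurrences(text, el))
        if not occ:
            return text
        for p, L in occ:
            for i in range(p - 1, min(p - 1 + L, length)):
                region[i] = NT[rng.integers(4)]
    raise GenerationError("background screening did not converge")


def _plant_elements(rng, background: str, counts, elements) -> str | None:
    length = len(background)
    region = list(background)
    occupied: list[tuple[int, int]] = []
    for el, k in zip(elements, counts):
        L = len(el.consensus)
        for _ in range(k):
            for _try in range(200):
                p = int(rng.integers(0, length - L + 1))
                # 1-base padding so planted instances cannot fuse
                if all(p + L + 1 <= s or p >= e + 1 for s, e in occupied):
                    break
            else:
                return None
            inst = "".join(
                c if c in NT else rng.choice(list({"R": "AG", "Y": "CT", "S": "CG",
                                                   "W": "AT", "K": "GT", "M": "AC",
                                                   "N": "ACGT"}[c]))
                for c in el.consensus
            )
            region[p : p + L] = inst
            occupied.append((p, p + L))
    return "".join(region)


# --- coding sequences and ESTs -------------------------------------------


def protein_to_cds(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with independently uniform synonymous codon choice
    per site (plus a random stop), so paralogous proteins diverge at the
    nucleotide level."""
    codons = [GENETIC_CODE[aa][rng.integers(len(GENETIC_CODE[aa]))] for aa in protein]
    codons.append(STOP_CODONS[rng.integers(3)])
    return "".join(codons)


def make_ests(
    gene_id: str,
    cds: str,
    count: int,
    rng: np.random.Generator,
    divergence: float,
    length_range: tuple[int, int] = (200, 500),
) -> list[str]:
    """EST fragments: length uniform in ``length_range``, start uniform over
    the CDS, per-base substitution error ``divergence``, random strand."""
    out = []
    for _ in range(count):
        ln = min(int(rng.integers(length_range[0], length_range[1] + 1)), len(cds))
        start = int(rng.integers(0, len(cds) - ln + 1))
        frag = list(cds[start : start + ln])
        for i in range(len(frag)):
            if rng.random() < divergence:
                frag[i] = NT.replace(frag[i], "")[rng.integers(3)]
        seq = "".join(frag)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        out.append(seq)
    return out


# --- placement ------------------------------------------------------------


@dataclass
class _GenePlan:
    key: str  # provisional key before positional ids are assigned
    cls: str  # CNL/NL/CN/XN/nonregular/background
    family: int | None  # family index or None
    cluster: int | None  # cluster index or None
    chromosome: str = ""
    start: int = 0
    strand: str = "+"


def _assign_classes(cfg: GeneratorConfig, rng) -> tuple[list[list[str]], list[str]]:
    """Class label per family (all members share it) and per singleton."""
    if cfg.quota_mode:
        quotas = dict(cfg.class_counts)
    else:
        classes = list(cfg.class_counts)
        weights = np.array([cfg.class_counts[c] for c in classes], dtype=float)
        draw = rng.multinomial(cfg.n_regular, weights / weights.sum())
        quotas = dict(zip(classes, (int(x) for x in draw)))
    n_family_genes = sum(cfg.family_sizes)
    if n_family_genes > cfg.n_regular:
        raise GenerationError("family sizes exceed the number of regular genes")
    # families need classes with enough quota; CNL takes most, and one pair
    # each of NL and CN when available (families never span classes)
    fam_classes: list[str] = []
    remaining = dict(quotas)
    sizes = sorted(cfg.family_sizes, reverse=True)
    wanted_minor = [c for c in ("NL", "CN") if remaining.get(c, 0) >= 2]
    minor_budget = {c: 1 for c in wanted_minor}
    for size in sizes:
        pick = None
        if size == 2:
            for c in wanted_minor:
                if minor_budget.get(c, 0) and remaining.get(c, 0) >= 2:
                    pick = c
                    minor_budget[c] -= 1
                    break
        if pick is None:
            for c in sorted(remaining, key=lambda c: -remaining[c]):
                if remaining[c] >= size:
                    pick = c
                    break
        if pick is None:
            raise GenerationError("cannot assign classes to families under quotas")
        remaining[pick] -= size
        fam_classes.append(pick)
    singles = [c for c in sorted(remaining) for _ in range(remaining[c])]
    rng.shuffle(singles)
    # fam_classes is aligned with family sizes sorted in descending order
    return fam_classes, singles


def generate(config: GeneratorConfig | None = None, outdir: str | Path | None = None) -> SyntheticGenome:
    """Generate genome, annotation, proteome, EST library and truth.

    Deterministic for a fixed config (seed included); writes the standard
    files when ``outdir`` is given."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    arch_rng = np.random.default_rng(rng.integers(2**31))
    place_rng = np.random.default_rng(rng.integers(2**31))
    prom_rng = np.random.default_rng(rng.integers(2**31))
    cds_rng = np.random.default_rng(rng.integers(2**31))
    est_rng = np.random.default_rng(rng.integers(2**31))
    genome_rng = np.random.default_rng(rng.integers(2**31))

    architect = _Architect(cfg, arch_rng)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    # ---- plan families, clusters, classes
    sizes = sorted(cfg.family_sizes, reverse=True)
    fam_classes, single_classes = _assign_classes(cfg, place_rng)
    n_seg = min(cfg.n_segmental_families, sum(1 for s in sizes if s == 2))
    if n_seg and cfg.n_chromosomes < 2:
        raise GenerationError("segmental families need at least two chromosomes")
    # the segmental families are size-2 CNL families taken from the tail
    seg_fams = [i for i, s in enumerate(sizes) if s == 2 and fam_classes[i] == "CNL"][:n_seg]

    cluster_hosts = list(cfg.cluster_chromosomes or [])
    if not cluster_hosts:
        cluster_hosts = [c for c in (0, 1, 3) if c < cfg.n_chromosomes] or [0]
        cluster_hosts = [chroms[i] for i in cluster_hosts]
    cluster_sizes = sorted(cfg.cluster_sizes, reverse=True)
    cluster_chrom = [cluster_hosts[i % len(cluster_hosts)] for i in range(len(cluster_sizes))]

    plans: list[_GenePlan] = []
    serial = [0]

    def new_plan(cls, family, cluster) -> _GenePlan:
        serial[0] += 1
        p = _GenePlan(key=f"k{serial[0]:04d}", cls=cls, family=family, cluster=cluster)
        plans.append(p)
        return p

    # pack non-segmental families into clusters (first fit, largest first)
    cluster_free = list(cluster_sizes)
    fam_order = [i for i in range(len(sizes)) if i not in seg_fams]
    fam_cluster: dict[int, int | None] = {}
    for fi in fam_order:
        placed = None
        for ci in range(len(cluster_free)):
            if cluster_free[ci] >= sizes[fi]:
                placed = ci
                cluster_free[ci] -= sizes[fi]
                break
        fam_cluster[fi] = placed
    for fi in seg_fams:
        fam_cluster[fi] = None

    singles_pool = list(single_classes)
    for fi, size in enumerate(sizes):
        for _ in range(size):
            new_plan(fam_classes[fi], fi, fam_cluster[fi])
    # leftover cluster slots are singleton regular genes
    for ci, free in enumerate(cluster_free):
        for _ in range(free):
            if not singles_pool:
                raise GenerationError("not enough singleton genes to fill clusters")
            new_plan(singles_pool.pop(), None, ci)
    for cls in singles_pool:
        new_plan(cls, None, None)
    for _ in range(cfg.n_nonregular):
        new_plan("nonregular", None, None)
    for _ in range(cfg.n_background):
        new_plan("background", None, None)

    # ---- chromosome layout
    by_cluster: dict[int, list[_GenePlan]] = {}
    isolated: list[_GenePlan] = []
    for p in plans:
        if p.cluster is not None:
            by_cluster.setdefault(p.cluster, []).append(p)
        else:
            isolated.append(p)
    # segmental family members go to distinct chromosomes; other family
    # groups stay on one chromosome (kept adjacent in the unit list)
    units: dict[str, list[list[_GenePlan]]] = {c: [] for c in chroms}
    for ci, members in sorted(by_cluster.items()):
        units[cluster_chrom[ci]].append(members)
    seg_pairs: list[tuple[_GenePlan, _GenePlan]] = []
    iso_groups: dict[tuple, list[_GenePlan]] = {}
    loose: list[_GenePlan] = []
    for p in isolated:
        if p.family is not None and p.family in seg_fams:
            iso_groups.setdefault(("seg", p.family), []).append(p)
        elif p.family is not None:
            iso_groups.setdefault(("fam", p.family), []).append(p)
        else:
            loose.append(p)
    rr = 0
    for key, group in sorted(iso_groups.items()):
        if key[0] == "seg":
            a, b = group
            units[chroms[rr % len(chroms)]].append([a])
            units[chroms[(rr + 1) % len(chroms)]].append([b])
            rr += 2
            seg_pairs.append((a, b))
        else:
            units[chroms[rr % len(chroms)]].append(group)
            rr += 1
    for p in loose:
        units[chroms[rr % len(chroms)]].append([p])
        rr += 1

    slot_pitch = 8000
    for chrom in chroms:
        chrom_units = units[chrom]
        place_rng.shuffle(chrom_units)
        cursor = 50_000
        for unit in chrom_units:
            if len(unit) == 1 and unit[0].cluster is None:
                g = unit[0]
                g.chromosome, g.start = chrom, cursor + int(place_rng.integers(0, 20_000))
                cursor = g.start + cfg.gene_spacing
            elif unit and unit[0].cluster is not None:
                base = cursor
                k = len(unit)
                nslots = (cfg.cluster_window - slot_pitch) // slot_pitch
                if k > nslots:
                    raise GenerationError("cluster too large for the window")
                slots = np.sort(place_rng.choice(nslots, size=k, replace=False))
                for g, s in zip(unit, slots):
                    g.chromosome = chrom
                    g.start = base + int(s) * slot_pitch + int(place_rng.integers(0, 2000))
                cursor = max(g.start for g in unit) + cfg.gene_spacing
            else:  # family group placed as adjacent isolated genes
                for g in unit:
                    g.chromosome, g.start = chrom, cursor
                    cursor += cfg.gene_spacing
        needed = cursor + cfg.promoter_length + 10_000
        if needed > cfg.chromosome_length:
            raise GenerationError(
                f"chromosome_length too short: {chrom} needs >= {needed} bp"
            )
    # fix any cluster units that ended up in the 'family group' branch
    # (family inside cluster is handled by the cluster branch above)

    # ---- build ancestors and member proteins
    blueprint_cache: dict[tuple, _Blueprint] = {}
    refs: dict[str, str] = {}
    proteins: dict[str, str] = {}
    arch_of: dict[str, DomainArchitecture] = {}

    def ancestor_for(p: _GenePlan) -> tuple[str, _Blueprint]:
        key = ("fam", p.family) if p.family is not None else ("solo", p.key)
        if key not in blueprint_cache:
            if p.cls == "background":
                raise AssertionError
            bp = architect.build(p.cls if p.cls != "nonregular" else "nonregular", arch_rng)
            blueprint_cache[key] = bp
        bp = blueprint_cache[key]
        ref_id = f"anc_fam{p.family:02d}" if p.family is not None else f"anc_{p.key}"
        refs.setdefault(ref_id, bp.protein)
        return ref_id, bp

    ancestor_of: dict[str, str] = {}
    for p in sorted(plans, key=lambda q: q.key):
        if p.cls == "background":
            for _ in range(60):
                prot = random_protein(arch_rng, int(arch_rng.integers(250, 401)))
                arch = analyze_protein(p.key, prot)
                if "NBS" not in arch.domains and len(arch.nbs_motifs_found) < 3:
                    break
            else:
                raise GenerationError("could not build background protein")
            proteins[p.key] = prot
            arch_of[p.key] = arch
            continue
        ref_id, bp = ancestor_for(p)
        ancestor_of[p.key] = ref_id
        for _ in range(60):
            member = mutate_protein(bp.protein, cfg.member_divergence, arch_rng, bp.protected)
            arch = analyze_protein(p.key, member)
            if _architecture_ok(bp, arch):
                break
        else:
            raise GenerationError(f"could not derive a clean {p.cls} member")
        proteins[p.key] = member
        arch_of[p.key] = arch

    # ---- positional gene ids, CDS, promoters, genome assembly
    plans.sort(key=lambda p: (p.chromosome, p.start, p.key))
    per_chrom_serial: dict[str, int] = {}
    key_to_id: dict[str, str] = {}
    for p in plans:
        per_chrom_serial[p.chromosome] = per_chrom_serial.get(p.chromosome, 0) + 1
        gid = f"{p.chromosome}g{per_chrom_serial[p.chromosome]:03d}"
        key_to_id[p.key] = gid
        p.strand = "+" if place_rng.random() < 0.5 else "-"

    chrom_arrays = {
        c: genome_rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=cfg.chromosome_length)
        for c in chroms
    }

    genes: list[GeneModel] = []
    cds_map: dict[str, str] = {}
    promoters: dict[str, str] = {}
    promoter_counts: dict[str, tuple[int, int, int]] = {}
    proteins_by_id: dict[str, str] = {}

    for p in plans:
        gid = key_to_id[p.key]
        prot = proteins[p.key]
        proteins_by_id[gid] = prot
        cds = protein_to_cds(prot, cds_rng)
        cds_map[gid] = cds
        promoter, counts = generate_promoter(
            prom_rng, cfg.promoter_means, cfg.promoter_length
        )
        promoters[gid] = promoter
        promoter_counts[gid] = counts
        start = p.start
        end = start + len(cds) - 1
        arr = chrom_arrays[p.chromosome]
        if p.strand == "+":
            body = cds
            prom_genomic = promoter
            arr[start - 1 - cfg.promoter_length : start - 1] = np.frombuffer(
                prom_genomic.encode(), dtype=np.uint8
            )
        else:
            body = reverse_complement(cds)
            prom_genomic = reverse_complement(promoter)
            arr[end : end + cfg.promoter_length] = np.frombuffer(
                prom_genomic.encode(), dtype=np.uint8
            )
        arr[start - 1 : end] = np.frombuffer(body.encode(), dtype=np.uint8)
        genes.append(
            GeneModel(
                gene_id=gid,
                chromosome=p.chromosome,
                start=start,
                end=end,
                strand=p.strand,
                exons=[(start, end)],
                cds_sequence=cds,
                protein_sequence=prot,
            )
        )

    chromosomes = {c: chrom_arrays[c].tobytes().decode() for c in chroms}

    # ---- ESTs
    regular_ids = [key_to_id[p.key] for p in plans if p.cls in cfg.class_counts]
    single_regular = [
        key_to_id[p.key] for p in plans if p.cls in cfg.class_counts and p.family is None
    ]
    n_unsupported = round(cfg.est_unsupported_fraction * len(regular_ids))
    if n_unsupported > len(single_regular):
        raise GenerationError("not enough singleton genes to leave unsupported")
    unsupported = set(
        np.array(sorted(single_regular))[
            est_rng.choice(len(single_regular), size=n_unsupported, replace=False)
        ]
    )
    est_counts: dict[str, int] = {}
    ests: list[tuple[str, str]] = []
    for p in plans:
        gid = key_to_id[p.key]
        if gid in unsupported:
            est_counts[gid] = 0
            continue
        if p.cls in cfg.class_counts:
            count = 1 + int(est_rng.poisson(max(cfg.est_mean_coverage - 1, 0)))
        else:
            count = int(est_rng.poisson(cfg.est_mean_coverage))
        est_counts[gid] = count
        for frag in make_ests(gid, cds_map[gid], count, est_rng, cfg.est_divergence):
            ests.append((f"est{len(ests) + 1:05d}", frag))

    # ---- truth
    families = []
    fam_members: dict[int, set[str]] = {}
    for p in plans:
        if p.family is not None:
            fam_members.setdefault(p.family, set()).add(key_to_id[p.key])
    families = [frozenset(v) for _k, v in sorted(fam_members.items())]
    cluster_members: dict[int, set[str]] = {}
    for p in plans:
        if p.cluster is not None:
            cluster_members.setdefault(p.cluster, set()).add(key_to_id[p.key])
    clusters = [
        (cluster_chrom[ci], frozenset(v)) for ci, v in sorted(cluster_members.items())
    ]
    label_of = {}
    for p in plans:
        label_of[key_to_id[p.key]] = p.cls
    truth = SyntheticTruth(
        architectures={key_to_id[p.key]: arch_of[p.key].domains for p in plans},
        class_labels=label_of,
        families=families,
        clusters=clusters,
        promoter_counts=promoter_counts,
        est_counts=est_counts,
        ancestor_of={key_to_id[k]: v for k, v in ancestor_of.items()},
        segmental_pairs=sorted(
            tuple(sorted((key_to_id[a.key], key_to_id[b.key]))) for a, b in seg_pairs
        ),
    )

    result = SyntheticGenome(
        config=cfg,
        chromosomes=chromosomes,
        genes=genes,
        proteins=proteins_by_id,
        cds=cds_map,
        promoters=promoters,
        ests=ests,
        refs=refs,
        truth=truth,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def truth_report(truth: SyntheticTruth):
    """One row per planted gene: class, family, cluster, promoter element
    counts and EST count."""
    import pandas as pd

    fam_of = {}
    for i, members in enumerate(truth.families, 1):
        for g in members:
            fam_of[g] = f"fam{i:03d}"
    clu_of = {}
    for i, (_c, members) in enumerate(truth.clusters, 1):
        for g in members:
            clu_of[g] = f"cluster{i:02d}"
    rows = []
    for gid in sorted(truth.class_labels):
        w, c, g = truth.promoter_counts[gid]
        rows.append(
            {
                "gene_id": gid,
                "class": truth.class_labels[gid],
                "architecture": "-".join(truth.architectures[gid]),
                "family_id": fam_of.get(gid, ""),
                "cluster_id": clu_of.get(gid, ""),
                "wbox": w,
                "cbf": c,
                "gcc": g,
                "est_count": truth.est_counts[gid],
            }
        )
    cols = ["gene_id", "class", "architecture", "family_id", "cluster_id", "wbox", "cbf", "gcc", "est_count"]
    return pd.DataFrame(rows, columns=cols)
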