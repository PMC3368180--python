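"""Detection of CC, NBS and LRR domains in protein sequences.

The NBS domain is called from a fixed library of twenty degenerate consensus
motifs (shipped in ``data/motifs.tsv``), eight of which carry the canonical
NBS labels (P-loop, RNBS-A, Kinase-2, RNBS-B, RNBS-C, GLPL, RNBS-D, MHDV).
An NBS domain is present when at least five of the eight labels hit and the
best hits occur in canonical order.  LRR repeats follow the consensus
LxxLxLxxNxL with an aliphatic set for L and {N,T,S,C} for N; at least two
repeats make an LRR domain.  Coiled-coils are scored by sliding-window
heptad-propensity geometric means converted to probabilities through a
two-Gaussian model.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

CANONICAL_LABELS = (
    "P-loop",
    "RNBS-A",
    "Kinase-2",
    "RNBS-B",
    "RNBS-C",
    "GLPL",
    "RNBS-D",
    "MHDV",
)
_LABEL_RANK = {lab: i for i, lab in enumerate(CANONICAL_LABELS)}

#: residues accepted at 'L' positions of the LRR consensus (aliphatic set)
LRR_ALIPHATIC = frozenset("LIVMFA")
#: residues accepted at the 'N' position (asparagine/threonine/serine/cysteine)
LRR_POLAR = frozenset("NTSC")
LRR_CONSENSUS = "LxxLxLxxNxL"

#: minimum length of an unassigned N-terminal segment reported as 'X'
X_SEGMENT_MIN = 10

DEFAULT_MAX_MISMATCH_FRACTION = 0.4
#: hard cap on mismatches inside a motif's conserved (bolded) core
CORE_MAX_MISMATCH = 1

# Q(L/I/V)RD: the short N-terminal motif shared by CC-type genes.
QLIVRD = "Q(L/I/V)RD"


def encode_protein(protein: str) -> np.ndarray:
    """Map a protein string to integer codes; non-standard residues get 20
    (matching nothing)."""
    return np.fromiter(
        (_AA_INDEX.get(c, 20) for c in protein.upper()), dtype=np.int8, count=len(protein)
    )


def parse_consensus(raw: str) -> list[frozenset[str]]:
    """Parse a consensus with alternative syntax, e.g. ``Q(L/I/V)RD`` ->
    [{Q},{L,I,V},{R},{D}]."""
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(raw):
        c = raw[i]
        if c == "(":
            j = raw.index(")", i)
            positions.append(frozenset(raw[i + 1 : j].replace("/", "")))
            i = j + 1
        else:
            positions.append(frozenset(c))
            i += 1
    return positions


@dataclass(frozen=True)
class MotifDefinition:
    """One consensus motif; ``nbs_label`` places it on the canonical NBS map
    (or 'CC-assoc'/'other')."""

    motif_id: int
    nbs_label: str
    consensus: str
    bold_core: str = ""
    positions: tuple[frozenset[str], ...] = field(default=(), compare=False)
    core_start: int = field(default=-1, compare=False)

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty consensus")
        object.__setattr__(self, "positions", tuple(parse_consensus(self.consensus)))
        if self.bold_core:
            idx = self.consensus.index(self.bold_core)
            # map raw-string index to position index (only exact for plain
            # consensi, which is what the shipped table contains)
            object.__setattr__(self, "core_start", idx)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def match_matrix(self) -> np.ndarray:
        """Boolean (len, 21) matrix: position x residue-code acceptance."""
        m = np.zeros((len(self.positions), 21), dtype=bool)
        for j, allowed in enumerate(self.positions):
            for a in allowed:
                if a in _AA_INDEX:
                    m[j, _AA_INDEX[a]] = True
        return m


@dataclass(frozen=True)
class MotifHit:
    motif_id: int
    start: int  # 1-based position in the protein
    end: int
    score: float  # fraction of matched positions

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0) or self.start > self.end:
            raise ValueError("invalid motif hit")


@lru_cache(maxsize=1)
def load_motifs() -> list[MotifDefinition]:
    """The packaged consensus motif library (Table of twenty MEME-style
    consensi with canonical NBS labels)."""
    text = (
        importlib.resources.files("rgene_atlas").joinpath("data/motifs.tsv").read_text()
    )
    motifs = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        motif_id, label, consensus = int(parts[0]), parts[1], parts[2]
        core = parts[3] if len(parts) > 3 else ""
        motifs.append(MotifDefinition(motif_id, label, consensus, core))
    return motifs


@lru_cache(maxsize=64)
def _match_matrix_cached(motif: MotifDefinition) -> np.ndarray:
    return motif.match_matrix


def scan_protein_motif(
    protein: str | np.ndarray,
    motif: MotifDefinition,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> list[MotifHit]:
    """Report every window whose mismatch fraction is <= the threshold and,
    when the motif declares a conserved core, whose core carries at most
    :data:`CORE_MAX_MISMATCH` mismatches.  Hits are sorted by start."""
    if not 0 <= max_mismatch_fraction < 1:
        raise ValueError("max_mismatch_fraction must be in [0, 1)")
    arr = protein if isinstance(protein, np.ndarray) else encode_protein(protein)
    L = len(motif)
    n = len(arr)
    if L > n:
        return []
    mm = _match_matrix_cached(motif)
    nwin = n - L + 1
    matches = np.zeros(nwin, dtype=np.int32)
    for j in range(L):
        matches += mm[j][arr[j : j + nwin]]
    budget = int(np.floor(max_mismatch_fraction * L))
    ok = (L - matches) <= budget
    if motif.core_start >= 0:
        cs, cl = motif.core_start, len(motif.bold_core)
        core_matches = np.zeros(nwin, dtype=np.int32)
        for j in range(cs, cs + cl):
            core_matches += mm[j][arr[j : j + nwin]]
        ok &= (cl - core_matches) <= CORE_MAX_MISMATCH
    hits = [
        MotifHit(motif.motif_id, int(i) + 1, int(i) + L, float(matches[i]) / L)
        for i in np.nonzero(ok)[0]
    ]
    return hits


def best_hits_by_label(
    protein: str | np.ndarray,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> dict[str, MotifHit]:
    """Best hit per canonical NBS label over all motifs carrying that label.

    The best hit maximises score; ties break on earlier start, then lower
    motif_id."""
    arr = protein if isinstance(protein, np.ndarray) else encode_protein(protein)
    best: dict[str, MotifHit] = {}
    for motif in load_motifs():
        if motif.nbs_label not in _LABEL_RANK:
            continue
        for hit in scan_protein_motif(arr, motif, max_mismatch_fraction):
            cur = best.get(motif.nbs_label)
            if cur is None or (-hit.score, hit.start, hit.motif_id) < (
                -cur.score,
                cur.start,
                cur.motif_id,
            ):
                best[motif.nbs_label] = hit
    return best


def detect_nbs(
    protein: str | np.ndarray,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    min_motifs: int = 5,
    offset: int = 0,
) -> tuple[bool, set[str], tuple[int, int] | None]:
    """NBS present iff >= ``min_motifs`` of the eight canonical labels hit
    and the found labels' best hits appear in canonical order
    P-loop < RNBS-A < Kinase-2 < RNBS-B < RNBS-C < GLPL < RNBS-D < MHDV
    (order restricted to labels present).  The span runs from the first
    found motif start to the last found motif end."""
    best = best_hits_by_label(protein, max_mismatch_fraction)
    labels = set(best)
    if len(labels) < min_motifs:
        return False, labels, None
    ordered = sorted(best.items(), key=lambda kv: _LABEL_RANK[kv[0]])
    starts = [hit.start for _, hit in ordered]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        return False, labels, None
    span = (
        min(h.start for h in best.values()) + offset,
        max(h.end for h in best.values()) + offset,
    )
    return True, labels, span


def detect_lrr(
    protein: str, region_start: int = 1
) -> tuple[int, list[tuple[int, int]]]:
    """Count non-overlapping LxxLxLxxNxL matches at or after ``region_start``
    (1-based), scanning left to right greedily.  Returns (count, spans)."""
    seq = protein.upper()
    spans: list[tuple[int, int]] = []
    i = max(region_start - 1, 0)
    L = len(LRR_CONSENSUS)
    while i + L <= len(seq):
        w = seq[i : i + L]
        if (
            w[0] in LRR_ALIPHATIC
            and w[3] in LRR_ALIPHATIC
            and w[5] in LRR_ALIPHATIC
            and w[8] in LRR_POLAR
            and w[10] in LRR_ALIPHATIC
        ):
            spans.append((i + 1, i + L))
            i += L
        else:
            i += 1
    return len(spans), spans


# --- coiled-coil scoring -------------------------------------------------

#: heptad position weights: hydrophobic-core positions a and d dominate
HEPTAD_WEIGHTS = np.array([2.5, 1.0, 1.0, 2.5, 1.0, 1.0, 1.0])

#: two-Gaussian calibration (score-space mean, sd) per window size
GAUSSIAN_PARAMS = {
    14: ((2.02, 0.39), (0.80, 0.32)),
    21: ((1.94, 0.34), (0.80, 0.28)),
    28: ((1.89, 0.30), (0.80, 0.25)),
}

DEFAULT_CC_THRESHOLD = 0.9
CC_MIN_RUN = 14


@lru_cache(maxsize=1)
def load_propensities() -> np.ndarray:
    text = (
        importlib.resources.files("rgene_atlas")
        .joinpath("data/coils_propensities.tsv")
        .read_text()
    )
    prop = np.zeros(21)
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        res, val = line.split("\t")
        prop[_AA_INDEX[res]] = float(val)
    return prop


def coiled_coil_scan(
    protein: str | np.ndarray,
    window: int = 28,
    cc_weight: float = 1.0,
) -> np.ndarray:
    """Per-residue coiled-coil probability profile.

    Each window is scored as the weighted geometric mean of residue
    propensities under the best of the seven heptad register phases; the
    score is converted to a probability through P = Gcc / (Gcc + w * Gg)
    with the Gaussian calibration for the window size.  The per-residue
    probability is the maximum over all covering windows.  Proteins shorter
    than 14 residues yield an empty profile."""
    arr = protein if isinstance(protein, np.ndarray) else encode_protein(protein)
    n = len(arr)
    if n < 14:
        return np.zeros(0)
    window = min(window, n)
    # snap to the largest calibrated size that fits
    window = max(w for w in GAUSSIAN_PARAMS if w <= window)
    prop = load_propensities()
    with np.errstate(divide="ignore"):
        logp = np.where(prop > 0, np.log(np.where(prop > 0, prop, 1.0)), -np.inf)
    lp = logp[np.minimum(arr, 20)]
    lp[arr >= 20] = -np.inf
    nwin = n - window + 1
    best_ln = np.full(nwin, -np.inf)
    wsum = np.empty(window)
    for phase in range(7):
        for j in range(window):
            wsum[j] = HEPTAD_WEIGHTS[(j - phase) % 7]
        total_w = wsum.sum()
        acc = np.zeros(nwin)
        for j in range(window):
            acc += wsum[j] * lp[j : j + nwin]
        np.maximum(best_ln, acc / total_w, out=best_ln)
    score = np.exp(best_ln)
    (cc_mean, cc_sd), (g_mean, g_sd) = GAUSSIAN_PARAMS[window]
    gcc = np.exp(-0.5 * ((score - cc_mean) / cc_sd) ** 2) / cc_sd
    gg = np.exp(-0.5 * ((score - g_mean) / g_sd) ** 2) / g_sd
    pwin = gcc / (gcc + cc_weight * gg)
    profile = np.zeros(n)
    # per-residue probability = max over covering windows
    for i in range(nwin):
        np.maximum(profile[i : i + window], pwin[i], out=profile[i : i + window])
    return profile


def cc_segments(
    profile: np.ndarray,
    threshold: float = DEFAULT_CC_THRESHOLD,
    min_run: int = CC_MIN_RUN,
) -> list[tuple[int, int]]:
    """Maximal runs of >= min_run consecutive residues with probability >=
    threshold, as 1-based (start, end) spans."""
    above = profile >= threshold
    segments = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                segments.append((i + 1, j))
            i = j
        else:
            i += 1
    return segments


def detect_cc_nterm(
    protein: str,
    nbs_span: tuple[int, int] | None,
    cc_threshold: float = DEFAULT_CC_THRESHOLD,
) -> tuple[bool, float, int | None]:
    """CC at the N-terminus: a called coiled-coil segment, or a hit of the
    CC-associated motif (motif 8) or of Q(L/I/V)RD, starting before the NBS
    span.  Returns (present, max probability, leftmost CC evidence start)."""
    limit = nbs_span[0] if nbs_span else len(protein) + 1
    profile = coiled_coil_scan(protein)
    max_prob = float(profile.max()) if len(profile) else 0.0
    starts: list[int] = []
    for s, _e in cc_segments(profile, cc_threshold):
        if s < limit:
            starts.append(s)
    motif8 = next(m for m in load_motifs() if m.motif_id == 8)
    for hit in scan_protein_motif(protein, motif8):
        if hit.start < limit:
            starts.append(hit.start)
    qlivrd = MotifDefinition(0, "CC-assoc", QLIVRD)
    for hit in scan_protein_motif(protein, qlivrd, max_mismatch_fraction=0.0):
        if hit.start < limit:
            starts.append(hit.start)
    if starts:
        return True, max_prob, min(starts)
    return False, max_prob, None


@dataclass
class DomainArchitecture:
    """Ordered domain calls for one protein — the input to classification."""

    gene_id: str
    domains: list[str]
    nbs_motifs_found: set[str]
    lrr_repeat_count: int
    cc_probability: float
    nbs_span: tuple[int, int] | None = None
    lrr_spans: list[tuple[int, int]] = field(default_factory=list)
    cc_start: int | None = None


def analyze_protein(
    gene_id: str,
    protein: str,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    min_motifs: int = 5,
    cc_threshold: float = DEFAULT_CC_THRESHOLD,
) -> DomainArchitecture:
    """Full domain architecture of a protein: CC / X at the N-terminus, one
    or two NBS blocks, and the C-terminal LRR region."""
    arr = encode_protein(protein)
    present, labels, span = detect_nbs(arr, max_mismatch_fraction, min_motifs)
    spans = [span] if present else []
    if present:
        # a second NBS block (atypical CNNL architectures)
        tail_off = span[1]
        tail = arr[tail_off:]
        if len(tail) >= 20:
            p2, _l2, s2 = detect_nbs(tail, max_mismatch_fraction, min_motifs, offset=tail_off)
            if p2:
                spans.append(s2)
    lrr_from = spans[-1][1] + 1 if spans else 1
    lrr_count, lrr_spans = detect_lrr(protein, lrr_from)
    cc, cc_prob, cc_start = detect_cc_nterm(protein, span, cc_threshold)

    parts: list[tuple[int, str]] = []
    if cc:
        parts.append((cc_start or 1, "CC"))
    elif spans and spans[0][0] > X_SEGMENT_MIN:
        parts.append((1, "X"))
    for s in spans:
        parts.append((s[0], "NBS"))
    if lrr_count >= 2:
        parts.append((lrr_spans[0][0], "LRR"))
    parts.sort()
    return DomainArchitecture(
        gene_id=gene_id,
        domains=[p[1] for p in parts],
        nbs_motifs_found=labels,
        lrr_repeat_count=lrr_count,
        cc_probability=cc_prob,
        nbs_span=span,
        lrr_spans=lrr_spans,
        cc_start=cc_start,
    )
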