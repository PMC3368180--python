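"""Bootstrap neighbor-joining trees from aligned sequences.

Distances: Kimura two-parameter for nucleotide alignments (transitions and
transversions corrected separately) or Poisson-corrected for proteins.  The
tree is built by the Saitou-Nei agglomeration with deterministic
lexicographic tie-breaking; edge supports come from column-resampled
bootstrap replicates.  Applying a nucleotide substitution model to protein
alignments is meaningless, hence the explicit two-mode design.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

GAP_CHARS = set("-.?X*")
NT_AMBIGUOUS = set("NRYSWKMBDHV")
PURINES = set("AG")
PYRIMIDINES = set("CT")


class SaturatedDistanceError(ValueError):
    """The substitution correction is undefined (log-domain boundary)."""


@dataclass
class Node:
    """A node of an (un)rooted tree; leaves carry ``name``, internal nodes
    may carry an integer bootstrap ``support``."""

    name: str = ""
    children: list["Node"] = field(default_factory=list)
    branch_length: float = 0.0
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


def _paired_sites(seq_a: str, seq_b: str, protein: bool = False) -> list[tuple[str, str]]:
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    ambiguous = set() if protein else NT_AMBIGUOUS
    pairs = []
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in GAP_CHARS or b in GAP_CHARS or a in ambiguous or b in ambiguous:
            continue
        pairs.append((a, b))
    return pairs


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance: with P the transition and Q the
    transversion fraction over retained sites,
    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)].

    Sites with gaps or ambiguity codes are excluded pairwise.  Raises
    :class:`SaturatedDistanceError` at the log-domain boundary."""
    pairs = _paired_sites(seq_a, seq_b)
    if not pairs:
        raise ValueError("no comparable sites")
    n = len(pairs)
    transitions = transversions = 0
    for a, b in pairs:
        if a == b:
            continue
        if (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES):
            transitions += 1
        else:
            transversions += 1
    P, Q = transitions / n, transversions / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistanceError(f"saturated pair (P={P:.3f}, Q={Q:.3f})")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(seq_a: str, seq_b: str, protein: bool = False) -> float:
    pairs = _paired_sites(seq_a, seq_b, protein)
    if not pairs:
        raise ValueError("no comparable sites")
    return sum(a != b for a, b in pairs) / len(pairs)


def poisson_distance(seq_a: str, seq_b: str) -> float:
    """Poisson-corrected protein distance d = -ln(1 - p)."""
    p = p_distance(seq_a, seq_b, protein=True)
    if p >= 1:
        raise SaturatedDistanceError("saturated pair (p = 1)")
    return -math.log(1 - p)


def distance_matrix(
    alignment: list[tuple[str, str]], mode: str = "poisson"
) -> DistanceMatrix:
    taxa = [name for name, _ in alignment]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon names")
    fn = {"k2p": k2p_distance, "poisson": poisson_distance, "p": p_distance}[mode]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(alignment[i][1], alignment[j][1])
    return DistanceMatrix(taxa, d)


def _fast_distance_matrix(codes: np.ndarray, mode: str) -> np.ndarray:
    """Vectorised p/poisson distances for bootstrap replicates.

    ``codes`` is an (n_taxa, n_cols) integer matrix with no gaps (the
    trimmed alignments the pipeline feeds here are gap-free)."""
    n = codes.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        p = (codes[i + 1 :] != codes[i]).mean(axis=1)
        if mode == "poisson":
            if (p >= 1).any():
                raise SaturatedDistanceError("saturated pair (p = 1)")
            p = -np.log1p(-p)
        d[i, i + 1 :] = d[i + 1 :, i] = p
    return d


def nj(dist: DistanceMatrix) -> Node:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimising
    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k), with ties broken
    by lexicographic taxon-pair order; branch lengths by the standard
    formulas, clamped at zero (with a warning) when negative.  Returns an
    unrooted tree (trifurcating root) for n >= 3 taxa."""
    n = len(dist.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dist.d.astype(float).copy()
    nodes: list[Node] = [Node(name=t) for t in dist.taxa]
    # labels used for deterministic tie-breaking: smallest leaf name under
    # each working node
    labels = list(dist.taxa)
    active = list(range(n))
    clamped = False
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((labels[active[i]], labels[active[j]]))), (i, j))
            for i, j in ties
            if i < j
        )[1]
        i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node(children=[nodes[ai], nodes[aj]])
        nodes[ai].branch_length = li
        nodes[aj].branch_length = lj
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d[ai, :] = new_row
        d[:, ai] = new_row
        d[ai, ai] = 0.0
        nodes[ai] = parent
        labels[ai] = min(labels[ai], labels[aj])
        active.pop(j)
    # final three taxa join at the unrooted trifurcation
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lengths = [la, lb, lc]
    if min(lengths) < 0:
        clamped = True
        lengths = [max(x, 0.0) for x in lengths]
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    for node, ln in zip(root.children, lengths):
        node.branch_length = ln
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    return root


def bipartitions(tree: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the leaf set, each identified by the
    side not containing the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    parts: set[frozenset[str]] = set()

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset((node.name,))
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            parts.add(side)
        return below

    walk(tree)
    return parts


def bootstrap(
    alignment: list[tuple[str, str]],
    n_reps: int = 1000,
    seed: int = 0,
    distance_mode: str = "poisson",
) -> Node:
    """NJ tree with bootstrap supports.

    Columns are resampled with replacement per replicate; the support of an
    internal edge is the percentage of replicate trees containing the same
    bipartition.  Deterministic given the seed."""
    if len(alignment) < 3:
        raise ValueError("bootstrap requires at least 3 taxa")
    ncols = len(alignment[0][1])
    if ncols < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = nj(distance_matrix(alignment, distance_mode))
    taxa = [name for name, _ in alignment]
    codes = np.array([[ord(c) for c in seq.upper()] for _, seq in alignment])
    gapfree = not any(
        set(seq.upper()) & GAP_CHARS or (distance_mode != "poisson" and set(seq.upper()) & NT_AMBIGUOUS)
        for _, seq in alignment
    )
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        try:
            if gapfree and distance_mode in ("poisson", "p"):
                dm = DistanceMatrix(taxa, _fast_distance_matrix(codes[:, cols], distance_mode))
            else:
                resampled = [
                    (name, "".join(seq[c] for c in cols)) for name, seq in alignment
                ]
                dm = distance_matrix(resampled, distance_mode)
            rep = nj(dm)
        except (SaturatedDistanceError, ValueError):
            continue
        for part in bipartitions(rep):
            counts[part] = counts.get(part, 0) + 1
    for node, below in _internal_nodes_with_sides(tree):
        node.support = round(100.0 * counts.get(below, 0) / n_reps)
    return tree


def _internal_nodes_with_sides(tree: Node):
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    out = []

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset((node.name,))
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            out.append((node, side))
        return below

    walk(tree)
    return out


def gblocks_lite(
    alignment: list[tuple[str, str]],
    min_conserved_fraction: float = 0.5,
    max_gap_fraction: float = 0.5,
) -> tuple[list[tuple[str, str]], list[int]]:
    """Simplified conserved-block column filter.

    Removes columns whose gap fraction exceeds ``max_gap_fraction`` or
    whose modal-residue fraction (among non-gap residues) falls below
    ``min_conserved_fraction``.  Returns the trimmed alignment and the
    0-based retained-column map."""
    if not alignment:
        raise ValueError("empty alignment")
    seqs = [seq.upper() for _, seq in alignment]
    ncols = len(seqs[0])
    if any(len(s) != ncols for s in seqs):
        raise ValueError("ragged alignment")
    retained: list[int] = []
    for c in range(ncols):
        col = [s[c] for s in seqs]
        residues = [x for x in col if x not in GAP_CHARS]
        gap_frac = 1 - len(residues) / len(col)
        if gap_frac > max_gap_fraction:
            continue
        modal = max(residues.count(x) for x in set(residues))
        if modal / len(residues) < min_conserved_fraction:
            continue
        retained.append(c)
    if not retained:
        raise ValueError("all columns removed by gblocks_lite")
    trimmed = [(name, "".join(seq[c] for c in retained)) for (name, _), seq in zip(alignment, seqs)]
    return trimmed, retained


# --- Newick serialisation -------------------------------------------------


def to_newick(tree: Node) -> str:
    """Newick with branch lengths (6 decimals) and integer support labels
    on internal nodes; negative lengths are clamped to 0 with a warning."""

    def fmt(node: Node, is_root: bool) -> str:
        bl = node.branch_length
        if bl < 0:
            warnings.warn(f"negative branch length {bl} clamped to 0")
            bl = 0.0
        if node.is_leaf:
            return f"{node.name}:{bl:.6f}"
        inner = ",".join(fmt(c, False) for c in node.children)
        label = "" if node.support is None else str(int(node.support))
        return f"({inner}){label}" + ("" if is_root else f":{bl:.6f}")

    return fmt(tree, True) + ";"


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;:]+|:")


def from_newick(text: str) -> Node:
    """Parse the Newick dialect written by :func:`to_newick`."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick must end with ';'")
    pos = 0

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        # label (leaf name or internal support)
        m = re.match(r"[^(),;:]+", text[pos:])
        if m:
            label = m.group(0)
            if node.is_leaf:
                node.name = label
            else:
                node.support = int(float(label))
            pos += len(label)
        if pos < len(text) and text[pos] == ":":
            pos += 1
            m = re.match(r"[^(),;:]+", text[pos:])
            node.branch_length = float(m.group(0))
            pos += len(m.group(0))
        return node

    root = parse_clade()
    if text[pos] != ";":
        raise ValueError("trailing characters in newick")
    return root
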