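"""EST expression support at an identity threshold.

An EST supports a gene when a local alignment of at least ``min_overlap``
bases with identity >= ``min_identity`` exists between the EST and the CDS
on either strand.  Alignment is BLASTN-like: exact 11-mer seeds define
candidate diagonals which are extended by banded Smith-Waterman dynamic
programming (match +1, mismatch -2, gap -2.5); identity is matches over
alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import reverse_complement

SEED_K = 11
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_OVERLAP = 100
MATCH, MISMATCH, GAP = 1.0, -2.0, -2.5
BAND = 15


@dataclass
class ESTSupport:
    gene_id: str
    est_count: int

    @property
    def supported(self) -> bool:
        return self.est_count >= 1


def _seed_diagonals(est: str, cds: str, k: int = SEED_K) -> list[int]:
    """Diagonals (cds_pos - est_pos) carrying at least one exact k-mer
    match, de-duplicated to band-width resolution."""
    index: dict[str, list[int]] = {}
    for j in range(len(cds) - k + 1):
        index.setdefault(cds[j : j + k], []).append(j)
    diags: set[int] = set()
    for i in range(len(est) - k + 1):
        for j in index.get(est[i : i + k], ()):
            diags.add(j - i)
    merged: list[int] = []
    for d in sorted(diags):
        if not merged or d - merged[-1] > BAND:
            merged.append(d)
    return merged


def _banded_local(est: str, cds: str, diagonal: int, band: int = BAND) -> tuple[int, int]:
    """Best-scoring local alignment near a diagonal: (matches, columns).

    Linear gap costs let the within-row (left) dependency be resolved by a
    prefix maximum, so each DP row is fully vectorised; the traceback
    recomputes transitions from the stored score matrix."""
    m, n = len(est), len(cds)
    width = 2 * band + 1
    e = np.frombuffer(est.encode(), dtype=np.uint8)
    c = np.frombuffer(cds.encode(), dtype=np.uint8)
    H = np.zeros((m + 1, width))
    gidx = GAP * np.arange(width)
    best, best_cell = 0.0, (0, 0)
    # column k of row i holds cds position j = i + diagonal - band + k; the
    # band slides one step per row, so the in-band cds bytes of row i are a
    # plain slice of a padded copy (pad byte 0 marks out-of-range cells)
    cpad = np.zeros(m + 2 * band, dtype=np.uint8)
    t0 = max(0, band - diagonal)
    t1 = min(m + 2 * band, n + band - diagonal)
    if t0 < t1:
        cpad[t0:t1] = c[t0 + diagonal - band : t1 + diagonal - band]
    windows = np.lib.stride_tricks.sliding_window_view(cpad, width)[:m]
    submat = np.where(windows == e[:, None], MATCH, MISMATCH)
    invalid = windows == 0  # out-of-range cds positions
    up = np.empty(width)
    for i in range(1, m + 1):
        prev = H[i - 1]
        diag = prev + submat[i - 1]
        up[:-1] = prev[1:] + GAP  # (i-1, j) sits at k+1 in row i-1
        up[-1] = -np.inf
        base = np.maximum(np.maximum(diag, up), 0.0)
        base[invalid[i - 1]] = 0.0
        # left chains: row[k] = max(base[k], max_{k'<k} base[k'] + GAP*(k-k'))
        left = np.empty(width)
        left[0] = -np.inf
        left[1:] = np.maximum.accumulate((base - gidx)[:-1]) + gidx[1:]
        row = np.maximum(base, left)
        row[invalid[i - 1]] = 0.0
        H[i] = row
    i_best, k_best = np.unravel_index(int(H.argmax()), H.shape)
    best, best_cell = H[i_best, k_best], (int(i_best), int(k_best))
    if best <= 0:
        return 0, 0
    # traceback by transition recomputation (scores are exact binary floats)
    i, k = best_cell
    matches = columns = 0
    while i > 0 and H[i, k] > 0:
        j = i + diagonal - band + k
        prev = H[i - 1, k]
        ch_match = 1 <= j <= n and c[j - 1] == e[i - 1]
        sub = MATCH if ch_match else MISMATCH
        if H[i, k] == prev + sub:
            matches += int(ch_match)
            columns += 1
            i -= 1
        elif k + 1 < width and H[i, k] == H[i - 1, k + 1] + GAP:
            columns += 1
            i -= 1
            k += 1
        elif k > 0 and H[i, k] == H[i, k - 1] + GAP:
            columns += 1
            k -= 1
        else:
            break
    return matches, columns


def match_est(
    est: str,
    cds: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    both_strands: bool = True,
) -> bool:
    """True iff a seeded banded local alignment of >= min_overlap columns
    with identity >= min_identity exists on either strand."""
    if min_overlap < SEED_K:
        raise ValueError(f"min_overlap must be >= seed size {SEED_K}")
    est, cds = est.upper(), cds.upper()
    candidates = [est]
    if both_strands:
        candidates.append(reverse_complement(est))
    for query in candidates:
        for d in _seed_diagonals(query, cds):
            matches, columns = _banded_local(query, cds, d)
            if columns >= min_overlap and matches / columns >= min_identity:
                return True
    return False


#: at most this many banded extensions per gene/EST/strand combination;
#: candidates are ranked by seed support, so a genuine alignment (which
#: carries many co-diagonal seeds) is always extended first
MAX_DIAGONALS = 8

#: two-hit rule: a merged diagonal is extended only with at least this many
#: seeds.  A genuine >=100-bp alignment at >=90% identity carries ~10
#: co-diagonal 11-mer seeds in expectation; single stray seed collisions
#: (shared codon runs between unrelated genes) are skipped.
MIN_DIAGONAL_SEEDS = 2


def _candidate_diagonals(
    query: str, index: dict[str, list[tuple[str, int]]], k: int = SEED_K
) -> dict[str, list[int]]:
    """Per-gene seed diagonals of a query against a global inverted k-mer
    index, de-duplicated to band resolution, filtered by the two-hit rule
    and ranked by seed support."""
    diags: dict[str, dict[int, int]] = {}
    for i in range(len(query) - k + 1):
        for gid, j in index.get(query[i : i + k], ()):
            bucket = diags.setdefault(gid, {})
            bucket[j - i] = bucket.get(j - i, 0) + 1
    merged: dict[str, list[int]] = {}
    for gid, ds in diags.items():
        keep: list[tuple[int, int]] = []  # (diagonal, seed count)
        for d in sorted(ds):
            if not keep or d - keep[-1][0] > BAND:
                keep.append((d, ds[d]))
            else:
                keep[-1] = (keep[-1][0], keep[-1][1] + ds[d])
        keep = [t for t in keep if t[1] >= MIN_DIAGONAL_SEEDS]
        if not keep:
            continue
        keep.sort(key=lambda t: (-t[1], t[0]))
        merged[gid] = [d for d, _cnt in keep[:MAX_DIAGONALS]]
    return merged


def support_table(
    genes: dict[str, str],
    ests: list[tuple[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    best_hit_only: bool = False,
) -> tuple[list[ESTSupport], dict[str, float]]:
    """Per-gene EST counts plus the %-unsupported summary.

    By default an EST counts for every gene it matches; with
    ``best_hit_only`` it counts only for the gene with the best alignment
    identity (ties broken by columns, then gene id).  Candidate gene/EST
    pairs come from a shared inverted 11-mer index, so unrelated pairs are
    never aligned."""
    index: dict[str, list[tuple[str, int]]] = {}
    for gid, cds in genes.items():
        seq = cds.upper()
        for j in range(len(seq) - SEED_K + 1):
            index.setdefault(seq[j : j + SEED_K], []).append((gid, j))
    counts = {gid: 0 for gid in genes}
    for _est_id, est_seq in ests:
        est_seq = est_seq.upper()
        hits: dict[str, tuple[float, int]] = {}
        for query in (est_seq, reverse_complement(est_seq)):
            for gid, diags in _candidate_diagonals(query, index).items():
                if not best_hit_only and gid in hits:
                    continue  # already supported; only the flag matters
                cds = genes[gid].upper()
                for d in diags:
                    matches, columns = _banded_local(query, cds, d)
                    if columns >= min_overlap:
                        ident = matches / columns
                        if ident >= min_identity and (
                            gid not in hits or (ident, columns) > hits[gid]
                        ):
                            hits[gid] = (ident, columns)
                            if not best_hit_only:
                                break
        if best_hit_only:
            if hits:
                best_gid = min(hits, key=lambda g: (-hits[g][0], -hits[g][1], g))
                counts[best_gid] += 1
        else:
            for gid in hits:
                counts[gid] += 1
    supports = [ESTSupport(gid, counts[gid]) for gid in sorted(counts)]
    n = len(supports)
    unsupported = sum(not s.supported for s in supports)
    summary = {
        "n_genes": n,
        "n_unsupported": unsupported,
        "pct_unsupported": round(100.0 * unsupported / n) if n else 0,
    }
    return supports, summary
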