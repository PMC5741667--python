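"""Pairwise alignment engines.

Three tiers, all sharing one scoring convention for DNA (match +1,
mismatch -1, a gap run of length ``l`` scores ``-(5 + l)``, terminal gaps
free where noted):

* an exact ungapped fast path for equal-length, clearly homologous pairs
  (under the affine costs above, a gap pair only pays off if it converts
  seven or more mismatches into matches, which does not happen for
  substitution divergence below saturation — so the ungapped alignment is
  the optimum);
* a seed-anchored banded affine free-end-gap ("overlap") aligner compiled
  with numba, used for the bulk of copy-vs-copy and consensus-vs-window
  comparisons;
* Biopython's :class:`PairwiseAligner` full dynamic program as the fallback
  for pairs the band cannot anchor, and as the independent reference the
  test suite checks the banded engine against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from numba import njit

from .alphabet import encode

MATCH = 1
MISMATCH = -1
GAP_FIRST = -6  # first base of a gap run: open (-5) plus one extension (-1)
GAP_EXT = -1

_NEG = -(10**9)


@dataclass(frozen=True)
class AlignmentStats:
    """Core (end-gap-trimmed) statistics of one pairwise alignment."""

    matches: int
    columns: int  # aligned core columns, internal gaps included
    span_a: tuple[int, int]  # 0-based half-open core span on sequence a
    span_b: tuple[int, int]
    score: float

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    def coverage(self, len_a: int, len_b: int) -> tuple[float, float]:
        ca = (self.span_a[1] - self.span_a[0]) / len_a if len_a else 0.0
        cb = (self.span_b[1] - self.span_b[0]) / len_b if len_b else 0.0
        return ca, cb


def make_dna_aligner(mode: str = "global", free_end_gaps: bool = True) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_FIRST
    aligner.extend_gap_score = GAP_EXT
    if mode == "global" and free_end_gaps:
        try:
            aligner.open_end_gap_score = 0
            aligner.extend_end_gap_score = 0
        except AttributeError:  # Biopython < 1.88 naming
            aligner.end_open_gap_score = 0
            aligner.end_extend_gap_score = 0
    return aligner


def _stats_from_biopython(aln, a: str, b: str) -> AlignmentStats:
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return AlignmentStats(0, 0, (0, 0), (0, 0), float(aln.score))
    a0, a1 = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b0, b1 = int(blocks_b[0][0]), int(blocks_b[-1][1])
    diag = 0
    matches = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        diag += ea - sa
        seg_a = a[sa:ea]
        seg_b = b[sb:eb]
        matches += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
    columns = (a1 - a0) + (b1 - b0) - diag
    return AlignmentStats(matches, columns, (a0, a1), (b0, b1), float(aln.score))


def full_overlap_align(a: str, b: str) -> AlignmentStats:
    """Exact affine free-end-gap global alignment (Biopython DP)."""
    aligner = make_dna_aligner("global", free_end_gaps=True)
    return _stats_from_biopython(aligner.align(a, b)[0], a, b)


def ungapped_stats(a_arr: np.ndarray, b_arr: np.ndarray) -> AlignmentStats:
    """Column-wise comparison of two equal-length sequences."""
    if a_arr.size != b_arr.size:
        raise ValueError("ungapped fast path requires equal lengths")
    matches = int((a_arr == b_arr).sum())
    n = int(a_arr.size)
    score = matches * MATCH + (n - matches) * MISMATCH
    return AlignmentStats(matches, n, (0, n), (0, n), float(score))


def anchor_diagonals(a_arr: np.ndarray, b_arr: np.ndarray, k: int = 13) -> tuple[int, int] | None:
    """Diagonal band (center, half-spread) implied by shared k-mers, or None.

    The band must cover every well-supported diagonal so that alignments
    crossing internal indels stay inside it.
    """
    if a_arr.size < k or b_arr.size < k:
        return None
    index: dict[bytes, list[int]] = {}
    ab = a_arr.tobytes()
    bb = b_arr.tobytes()
    step = max(1, k // 2)
    for i in range(0, len(ab) - k + 1, step):
        index.setdefault(ab[i : i + k], []).append(i)
    votes: dict[int, int] = {}
    for j in range(0, len(bb) - k + 1):
        hits = index.get(bb[j : j + k])
        if hits:
            for i in hits:
                d = j - i
                votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    support = max(2, max(votes.values()) // 20)
    good = [d for d, v in votes.items() if v >= support] or list(votes)
    lo, hi = min(good), max(good)
    return (lo + hi) // 2, (hi - lo + 1) // 2


@njit(cache=True)
def _banded_overlap(a, b, diag, w, match, mismatch, gap_first, gap_ext):  # pragma: no cover
    n = a.size
    m = b.size
    W = 2 * w + 1
    NEG = -(10**9)
    M = np.full((n + 1, W), NEG, np.int64)
    X = np.full((n + 1, W), NEG, np.int64)  # gap in b (consumes a)
    Y = np.full((n + 1, W), NEG, np.int64)  # gap in a (consumes b)
    PM = np.zeros((n + 1, W), np.uint8)
    PX = np.zeros((n + 1, W), np.uint8)
    PY = np.zeros((n + 1, W), np.uint8)
    START = np.uint8(3)
    for i in range(n + 1):
        for c in range(W):
            j = i + diag + c - w
            if j < 0 or j > m:
                continue
            if i == 0 or j == 0:
                M[i, c] = 0
                PM[i, c] = START
                continue
            # M: diagonal predecessor shares the band column
            pm, px, py = M[i - 1, c], X[i - 1, c], Y[i - 1, c]
            best = pm
            ptr = np.uint8(0)
            if px > best:
                best, ptr = px, np.uint8(1)
            if py > best:
                best, ptr = py, np.uint8(2)
            if best > NEG // 2:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[i, c] = best + s
                PM[i, c] = ptr
            # X: vertical predecessor (i-1, j) -> band column c+1
            if c + 1 < W:
                fm = M[i - 1, c + 1] + gap_first
                fx = X[i - 1, c + 1] + gap_ext
                fy = Y[i - 1, c + 1] + gap_first
                best = fm
                ptr = np.uint8(0)
                if fx > best:
                    best, ptr = fx, np.uint8(1)
                if fy > best:
                    best, ptr = fy, np.uint8(2)
                if best > NEG // 2:
                    X[i, c] = best
                    PX[i, c] = ptr
            # Y: horizontal predecessor (i, j-1) -> band column c-1
            if c - 1 >= 0:
                fm = M[i, c - 1] + gap_first
                fy = Y[i, c - 1] + gap_ext
                fx = X[i, c - 1] + gap_first
                best = fm
                ptr = np.uint8(0)
                if fx > best:
                    best, ptr = fx, np.uint8(1)
                if fy > best:
                    best, ptr = fy, np.uint8(2)
                if best > NEG // 2:
                    Y[i, c] = best
                    PY[i, c] = ptr
    # best boundary cell: last row, or cells where j == m (free trailing gaps)
    best_score = NEG
    bi = -1
    bc = -1
    bs = np.uint8(0)
    for c in range(W):
        j = n + diag + c - w
        if 0 <= j <= m and M[n, c] > best_score:
            best_score, bi, bc, bs = M[n, c], n, c, np.uint8(0)
    for i in range(n + 1):
        c = m - i - diag + w
        if 0 <= c < W and M[i, c] > best_score:
            best_score, bi, bc, bs = M[i, c], i, c, np.uint8(0)
    if bi < 0:
        return NEG, 0, 0, 0, 0, 0, 0
    # traceback
    matches = 0
    columns = 0
    i, c, state = bi, bc, bs
    end_i = bi
    end_j = bi + diag + bc - w
    while True:
        j = i + diag + c - w
        if state == 0:
            if PM[i, c] == START:
                break
            columns += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            state = PM[i, c]
            i -= 1
            # c unchanged (diagonal move)
        elif state == 1:
            columns += 1
            state = PX[i, c]
            i -= 1
            c += 1
        else:
            columns += 1
            state = PY[i, c]
            c -= 1
    start_i = i
    start_j = i + diag + c - w
    return best_score, matches, columns, start_i, start_j, end_i, end_j


def overlap_align(a: str, b: str, band: int = 32) -> AlignmentStats:
    """Affine free-end-gap alignment of two homologous sequences.

    Equal-length pairs that are recognisably homologous (position-wise
    identity >= 0.5) take the exact ungapped path. Otherwise the pair is
    anchored on its most-voted shared-k-mer diagonal and aligned within a
    band; pairs with no shared k-mer fall back to the full dynamic program.
    """
    a_arr = encode(a)
    b_arr = encode(b)
    if a_arr.size == b_arr.size and a_arr.size > 0:
        stats = ungapped_stats(a_arr, b_arr)
        if stats.identity >= 0.5:
            return stats
    anchor = anchor_diagonals(a_arr, b_arr)
    if anchor is None:
        return full_overlap_align(a, b)
    diag, spread = anchor
    if spread > 400:  # diffuse anchoring; the band would not be trustworthy
        return full_overlap_align(a, b)
    w = max(band, spread + 32, abs(b_arr.size - a_arr.size - diag) + 16)
    out = _banded_overlap(
        a_arr, b_arr, diag, w,
        np.int64(MATCH), np.int64(MISMATCH), np.int64(GAP_FIRST), np.int64(GAP_EXT),
    )
    score, matches, columns, si, sj, ei, ej = out
    if score <= _NEG // 2 or columns == 0:
        return full_overlap_align(a, b)
    return AlignmentStats(int(matches), int(columns), (int(si), int(ei)), (int(sj), int(ej)), float(score))


def local_align(a: str, b: str) -> AlignmentStats:
    """Best local alignment (Smith-Waterman) under the shared DNA scoring."""
    aligner = make_dna_aligner("local")
    alns = aligner.align(a, b)
    if alns.score <= 0:
        return AlignmentStats(0, 0, (0, 0), (0, 0), 0.0)
    return _stats_from_biopython(alns[0], a, b)


def make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner
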