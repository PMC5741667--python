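"""ESCC-seed miRNA detection, family grouping and genomic copy counting.

The embryonic stem cell-specific cell-cycle (ESCC) seed is the hexamer
AAGUGC lying fully within the first eight nucleotides of a mature miRNA
(start positions 1-3, 1-based) — the signature of the miR-427/430/302 and
miR-93b families whose genomic expansion this package counts.
Sequences are normalised to the DNA alphabet internally; input alphabets
are preserved on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import overlap_align
from .alphabet import encode, revcomp, to_dna
from .errors import InputError

ESCC_SEED = "AAGTGC"  # DNA form of AAGUGC


def has_escc_seed(mature: str) -> bool:
    """True iff AAGUGC occurs fully within the first eight nucleotides."""
    if len(mature) < 8:
        raise InputError("mature sequence shorter than 8 nt")
    pos = to_dna(mature)[:8].find(ESCC_SEED)
    return 0 <= pos <= 2


@dataclass(frozen=True)
class MirnaHit:
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    mismatches: int


def _seed_span(mature_dna: str) -> tuple[int, int]:
    pos = mature_dna[:8].find(ESCC_SEED)
    if 0 <= pos <= 2:
        return pos, pos + 6
    return 1, 7  # canonical miRNA seed, nucleotides 2-7


def _scan_strand(seq_arr: np.ndarray, mat: np.ndarray, seed_lo: int, seed_hi: int,
                 max_mismatches: int) -> list[tuple[int, int]]:
    m = mat.size
    if seq_arr.size < m:
        return []
    win = np.lib.stride_tricks.sliding_window_view(seq_arr, m)
    mism = (win != mat[None, :])
    seed_ok = ~mism[:, seed_lo:seed_hi].any(axis=1)
    outside = mism.sum(axis=1) - mism[:, seed_lo:seed_hi].sum(axis=1)
    hits = np.where(seed_ok & (outside <= max_mismatches))[0]
    return [(int(p), int(outside[p])) for p in hits]


def scan_genome_for_copies(
    genome: dict[str, str] | str,
    mature: str,
    max_mismatches: int = 1,
) -> list[MirnaHit]:
    """Find genomic copies of a mature miRNA on both strands.

    The seed hexamer must match exactly; up to ``max_mismatches``
    substitutions are tolerated outside it. Overlapping hits are merged
    keeping the one with fewer mismatches ('+' strand, then leftmost, on
    ties).
    """
    mature_dna = to_dna(mature)
    if len(mature_dna) < 18:
        raise InputError("mature sequence shorter than 18 nt")
    if not 0 <= max_mismatches <= 3:
        raise InputError("max_mismatches must lie in [0, 3]")
    contigs = {"seq": genome} if isinstance(genome, str) else genome
    seed_lo, seed_hi = _seed_span(mature_dna)
    mat = encode(mature_dna)
    m = mat.size

    raw: list[MirnaHit] = []
    for contig, seq in contigs.items():
        seq = to_dna(seq)
        L = len(seq)
        fwd = encode(seq)
        for p, mm in _scan_strand(fwd, mat, seed_lo, seed_hi, max_mismatches):
            raw.append(MirnaHit(contig, p, p + m, "+", mm))
        rev = encode(revcomp(seq))
        for p, mm in _scan_strand(rev, mat, seed_lo, seed_hi, max_mismatches):
            raw.append(MirnaHit(contig, L - p - m, L - p, "-", mm))

    # merge overlapping hits, preferring fewer mismatches
    raw.sort(key=lambda h: (h.mismatches, 0 if h.strand == "+" else 1, h.contig, h.start))
    kept: list[MirnaHit] = []
    for h in raw:
        if all(h.contig != o.contig or h.end <= o.start or h.start >= o.end for o in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.start))
    return kept


@dataclass
class MirnaFamily:
    family_id: str
    seed: str
    representative_mature: str
    member_matures: list[str] = field(default_factory=list)

    @property
    def copy_count(self) -> int:
        return len(self.member_matures)


def _first8_hexamers(mature_dna: str) -> set[str]:
    return {mature_dna[i : i + 6] for i in range(0, 3) if len(mature_dna) >= i + 6}


def group_into_families(matures: list[str], min_identity: float = 0.8) -> list[MirnaFamily]:
    """Single-linkage clustering of mature sequences into seed families.

    Two matures link when they share a hexamer fully within their first
    eight nucleotides AND align with overall identity >= ``min_identity``.
    Each cluster's most frequent sequence (ties lexicographic) is the
    representative; the family seed is the members' most common
    first-eight hexamer, reported in the input alphabet.
    """
    if not matures:
        return []
    dna = [to_dna(m) for m in matures]
    for s in dna:
        if len(s) < 18:
            raise InputError("mature sequences must be >= 18 nt")
    n = len(dna)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    hexes = [_first8_hexamers(s) for s in dna]
    for i in range(n):
        for j in range(i + 1, n):
            if not hexes[i] & hexes[j]:
                continue
            if dna[i] == dna[j]:
                ident = 1.0
            else:
                stats = overlap_align(dna[i], dna[j])
                ident = stats.matches / max(len(dna[i]), len(dna[j]))
            if ident >= min_identity:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    is_rna = [("U" in m.upper() and "T" not in m.upper()) for m in matures]
    families: list[MirnaFamily] = []
    for k, members in sorted(clusters.items(), key=lambda kv: min(kv[1])):
        seqs = [dna[i] for i in members]
        freq: dict[str, int] = {}
        for s in seqs:
            freq[s] = freq.get(s, 0) + 1
        rep_dna = sorted(freq, key=lambda s: (-freq[s], s))[0]
        hex_freq: dict[str, int] = {}
        for i in members:
            esc = dna[i][:8].find(ESCC_SEED)
            key = dna[i][esc : esc + 6] if 0 <= esc <= 2 else sorted(hexes[i])[0]
            hex_freq[key] = hex_freq.get(key, 0) + 1
        seed = sorted(hex_freq, key=lambda s: (-hex_freq[s], s))[0]
        rep_idx = next(i for i in members if dna[i] == rep_dna)
        rep = matures[rep_idx]
        if is_rna[rep_idx]:
            seed = seed.replace("T", "U")
        families.append(
            MirnaFamily(
                family_id=f"family_{len(families) + 1}",
                seed=seed,
                representative_mature=rep,
                member_matures=[matures[i] for i in members],
            )
        )
    return families


def count_family_copies(
    genome: dict[str, str] | str,
    matures: dict[str, str],
    max_mismatches: int = 1,
) -> dict[str, int]:
    """Genomic copy count per family representative mature."""
    return {
        fam: len(scan_genome_for_copies(genome, mat, max_mismatches))
        for fam, mat in matures.items()
    }
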