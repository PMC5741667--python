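"""Canonical k-mer counting — the substrate of consensus extension.

Both strands pool into one count per canonical k-mer (the lexicographic
minimum of a k-mer and its reverse complement). k must be odd so no k-mer
is its own reverse complement and the canonical form is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import CODE, canonical
from .errors import InputError


@dataclass
class KmerTable:
    k: int
    counts: dict[str, int]

    def get(self, kmer: str) -> int:
        """Count of a k-mer's canonical form (0 if absent)."""
        return self.counts.get(canonical(kmer), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


def _as_sequences(genome) -> list[str]:
    if isinstance(genome, str):
        return [genome]
    if isinstance(genome, dict):
        return list(genome.values())
    return [str(s) for s in genome]


def count_kmers(genome, k: int = 25) -> KmerTable:
    """Count canonical k-mers over every length-k ACGT window.

    Windows containing a non-ACGT symbol are skipped. The total count mass
    therefore equals the number of valid windows.
    """
    if k % 2 == 0:
        raise InputError(f"k must be odd for unambiguous canonical k-mers (got {k})")
    if not 3 <= k <= 31:
        raise InputError(f"k must lie in [3, 31] (got {k})")
    seqs = [s for s in _as_sequences(genome) if s]
    if not seqs:
        raise InputError("genome is empty")

    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    rpowers = 4 ** np.arange(k, dtype=np.int64)
    agg: dict[int, int] = {}
    for seq in seqs:
        arr = CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
        if arr.size < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, k)
        valid = (win != 255).all(axis=1)
        if not valid.any():
            continue
        w = win[valid].astype(np.int64)
        fwd = w @ powers
        rev = (3 - w) @ rpowers
        canon = np.minimum(fwd, rev)
        codes, cnt = np.unique(canon, return_counts=True)
        for c, n in zip(codes.tolist(), cnt.tolist()):
            agg[c] = agg.get(c, 0) + n

    lut = "ACGT"
    counts: dict[str, int] = {}
    for code, n in agg.items():
        chars = []
        for _ in range(k):
            chars.append(lut[code & 3])
            code >>= 2
        counts["".join(reversed(chars))] = n
    return KmerTable(k=k, counts=counts)
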