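"""Nucleotide alphabet helpers shared across the package.

Sequences are plain uppercase DNA strings externally; hot loops work on
``numpy`` ``uint8`` arrays of ASCII codes. RNA input (U) is normalised to
DNA (T) at the boundary and the original alphabet restored on output where
it matters.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# ASCII code -> 0..3 for ACGT, 255 otherwise
CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    CODE[ord(_b)] = _i
    CODE[ord(_b.lower())] = _i

BASE_BYTES = np.frombuffer(BASES.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Pools the two strands of double-stranded sequence into one key.
    """
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def to_dna(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """ASCII byte view of a sequence (uint8)."""
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform ACGT background sequence."""
    return decode(rng.choice(BASE_BYTES, size=length))
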