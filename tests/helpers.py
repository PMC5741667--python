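"""Shared test utilities (independent of the library's alignment code)."""


def hamming_fraction(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


def best_orientation_identity(consensus: str, master: str):
    """Identity and coverage of a consensus against a master, strand-agnostic.

    Uses the full (Biopython) aligner, independent of the banded engine.
    """
    from repeatburst.align import full_overlap_align
    from repeatburst.alphabet import revcomp

    s1 = full_overlap_align(consensus, master)
    s2 = full_overlap_align(revcomp(consensus), master)
    return s1 if s1.matches >= s2.matches else s2
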