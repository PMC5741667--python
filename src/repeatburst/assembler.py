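"""Repeat consensus assembly by majority-vote k-mer extension.

A consensus is grown from the highest-count unconsumed canonical k-mer by
repeatedly appending the base whose extension k-mer has the highest
canonical count; extension stops at a count below ``min_count``, a tie
between the top two candidates (refusing to guess at family branch
points), a k-mer revisited within the growing contig (loop), or
``max_length``. All k-mers of a finished contig — emitted or discarded —
are marked consumed so each family is assembled once.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import BASES, canonical, revcomp
from .align import AlignmentStats, local_align, overlap_align
from .errors import InputError
from .kmers import KmerTable


@dataclass
class RepeatConsensus:
    consensus_id: str
    sequence: str
    seed_kmer: str
    mean_depth: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatCopy:
    contig: str
    start: int  # 0-based half-open, genome coordinates
    end: int
    strand: str
    identity_to_consensus: float
    sequence: str  # consensus orientation

    @property
    def length(self) -> int:
        return self.end - self.start


def _extend(seq: str, table: KmerTable, min_count: int, max_length: int,
            used: set[str], consumed: set[str], rightward: bool) -> str:
    k = table.k
    counts = table.counts
    while len(seq) < max_length:
        context = seq[-(k - 1):] if rightward else seq[: k - 1]
        scored = []
        for b in BASES:
            kmer = context + b if rightward else b + context
            scored.append((counts.get(canonical(kmer), 0), b, kmer))
        scored.sort(key=lambda t: (-t[0], t[1]))
        best_count, base, kmer = scored[0]
        if best_count < min_count:
            break
        if best_count == scored[1][0]:
            break  # majority vote tie: refuse to pick a branch arbitrarily
        ck = canonical(kmer)
        if ck in used:
            break  # loop within the growing contig
        if ck in consumed:
            break  # already part of a finished consensus: a family builds once
        used.add(ck)
        seq = seq + base if rightward else base + seq
    return seq


def assemble_consensus(
    table: KmerTable,
    min_count: int = 10,
    min_length: int = 1000,
    max_length: int = 20000,
) -> list[RepeatConsensus]:
    """Assemble repeat consensuses from a k-mer table.

    Deterministic given the table: seeds are taken in order of descending
    count (ties lexicographic), and the emitted list is sorted by
    descending mean constituent k-mer depth.
    """
    if min_count < 2:
        raise InputError("min_count must be >= 2")
    if min_length < table.k:
        raise InputError("min_length must be >= k")
    k = table.k
    counts = table.counts
    order = sorted(counts, key=lambda km: (-counts[km], km))
    consumed: set[str] = set()
    raw: list[tuple[str, str, float]] = []

    for seed in order:
        if seed in consumed or counts[seed] < min_count:
            continue
        used = {seed}
        seq = _extend(seed, table, min_count, max_length, used, consumed, rightward=True)
        seq = _extend(seq, table, min_count, max_length, used, consumed, rightward=False)
        kmers = {canonical(seq[i : i + k]) for i in range(len(seq) - k + 1)}
        consumed |= kmers
        if len(seq) >= min_length:
            depth = sum(counts.get(km, 0) for km in kmers) / len(kmers)
            raw.append((seq, seed, depth))

    raw.sort(key=lambda t: (-t[2], -len(t[0]), t[0]))
    return [
        RepeatConsensus(f"consensus_{i + 1}", seq, seed, depth)
        for i, (seq, seed, depth) in enumerate(raw)
    ]


def classify_consensus(
    consensus: RepeatConsensus | str,
    reference_library: dict[str, str],
    min_align_length: int = 500,
) -> tuple[str, AlignmentStats | None]:
    """Label a consensus by its longest qualifying local alignment.

    Both orientations of the consensus are compared against every
    reference; among hits with aligned length >= ``min_align_length`` the
    longest wins (ties: higher identity, then lexicographic label).
    Returns ("unknown", None) when nothing qualifies.
    """
    if not reference_library:
        raise InputError("reference library is empty")
    seq = consensus.sequence if isinstance(consensus, RepeatConsensus) else consensus
    best: tuple[int, float, str, AlignmentStats] | None = None
    for label in sorted(reference_library):
        ref = reference_library[label]
        for oriented in (seq, revcomp(seq)):
            stats = local_align(oriented, ref)
            if stats.columns < min_align_length:
                continue
            key = (stats.columns, stats.identity)
            if best is None or key > (best[0], best[1]) or (
                key == (best[0], best[1]) and label < best[2]
            ):
                best = (stats.columns, stats.identity, label, stats)
    if best is None:
        return "unknown", None
    return best[2], best[3]


def recover_copies(
    genome: dict[str, str] | str,
    consensus: RepeatConsensus | str,
    min_identity: float = 0.7,
    min_length: int = 1000,
    seed_k: int = 15,
    min_seed_hits: int = 3,
) -> list[RepeatCopy]:
    """Locate genomic copies of a consensus by seed-and-extend scanning.

    Exact ``seed_k``-mer hits on either strand are clustered by implied
    copy start; each candidate window is aligned to the consensus with the
    free-end-gap affine aligner, and hits with identity >= ``min_identity``
    over >= ``min_length`` aligned columns are reported. Overlapping hits
    are resolved by higher identity, then greater length. '-' strand hits
    return their sequence in consensus orientation.
    """
    cseq = consensus.sequence if isinstance(consensus, RepeatConsensus) else consensus
    if not 0.5 <= min_identity <= 1.0:
        raise InputError("min_identity must lie in [0.5, 1]")
    if len(cseq) < min_length:
        raise InputError("consensus shorter than min_length")
    contigs = {"seq": genome} if isinstance(genome, str) else genome
    L = len(cseq)

    index: dict[str, list[tuple[int, str]]] = {}
    for strand, oriented in (("+", cseq), ("-", revcomp(cseq))):
        for i in range(0, L - seed_k + 1):
            index.setdefault(oriented[i : i + seed_k], []).append((i, strand))

    hits: list[RepeatCopy] = []
    for contig, seq in contigs.items():
        # vote for implied (start, strand) of a full copy
        votes: dict[tuple[int, str], int] = {}
        for j in range(0, len(seq) - seed_k + 1):
            for cpos, strand in index.get(seq[j : j + seed_k], ()):
                votes[(j - cpos, strand)] = votes.get((j - cpos, strand), 0) + 1
        # cluster implied starts within half a consensus length, per strand
        for strand in ("+", "-"):
            starts = sorted(s for (s, st) in votes if st == strand)
            clusters: list[list[int]] = []
            for s in starts:
                if clusters and s - clusters[-1][-1] <= 50:
                    clusters[-1].append(s)
                else:
                    clusters.append([s])
            for cl in clusters:
                n_votes = sum(votes[(s, strand)] for s in cl)
                if n_votes < min_seed_hits:
                    continue
                w0 = max(0, min(cl) - 50)
                w1 = min(len(seq), max(cl) + L + 50)
                window = seq[w0:w1]
                oriented = cseq if strand == "+" else revcomp(cseq)
                stats = overlap_align(oriented, window)
                if stats.columns < min_length or stats.identity < min_identity:
                    continue
                g0 = w0 + stats.span_b[0]
                g1 = w0 + stats.span_b[1]
                found = seq[g0:g1]
                if strand == "-":
                    found = revcomp(found)
                hits.append(RepeatCopy(contig, g0, g1, strand, stats.identity, found))

    # resolve overlaps: keep higher identity, then longer, then leftmost
    hits.sort(key=lambda h: (-h.identity_to_consensus, -(h.end - h.start), h.contig, h.start))
    kept: list[RepeatCopy] = []
    for h in hits:
        if all(
            h.contig != o.contig or h.end <= o.start or h.start >= o.end for o in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.start))
    return kept
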