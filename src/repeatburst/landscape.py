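"""Divergence landscapes: pairwise distances, burst detection, domain retention.

The pairwise distance between two repeat copies is one minus their
identity over the aligned core of a free-end-gap global alignment
(terminal overhang columns excluded). A pair only enters the matrix if
that core covers a minimum fraction of BOTH copies; copies breaking the
coverage requirement are dropped, fewest-valid-pairs first, until every
retained pair qualifies.

Burst detection fits one-dimensional Gaussian mixtures with 1, 2 and 3
components to the distance values and selects the component count by ICL
(BIC plus twice the assignment entropy) — the standard criterion for
counting clusters rather than density components — requiring an
improvement margin over the next-simplest model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .align import make_protein_aligner, overlap_align
from .assembler import RepeatCopy
from .errors import InputError, InsufficientDataError


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, distances in [0, 1]
    kept_mask: np.ndarray  # over the input copies; True where retained

    def condensed(self) -> np.ndarray:
        """Flattened upper triangle (the input of detect_bursts)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for name, row in zip(self.labels, self.values):
            safe = name[:10].ljust(10)
            lines.append(safe + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def _copy_seqs(copies) -> tuple[list[str], list[str]]:
    seqs, labels = [], []
    for i, c in enumerate(copies):
        if isinstance(c, RepeatCopy):
            seqs.append(c.sequence)
            labels.append(f"{c.contig}_{c.start}_{c.end}_{c.strand}")
        elif isinstance(c, tuple):
            labels.append(c[0])
            seqs.append(c[1])
        else:
            seqs.append(str(c))
            labels.append(f"copy_{i + 1}")
    return seqs, labels


def pairwise_distances(copies, min_mutual_coverage: float = 0.8) -> DistanceMatrix:
    """All-against-all aligned-core distances with a mutual coverage filter.

    ``copies`` may be strings, (label, sequence) tuples or RepeatCopy
    objects. Raises InsufficientDataError if fewer than three copies
    survive the filter.
    """
    seqs, labels = _copy_seqs(copies)
    n = len(seqs)
    if n < 3:
        raise InsufficientDataError("need at least 3 copies")
    if not 0 < min_mutual_coverage <= 1:
        raise InputError("min_mutual_coverage must lie in (0, 1]")

    dist = np.zeros((n, n))
    valid = np.ones((n, n), bool)
    for i in range(n):
        for j in range(i + 1, n):
            stats = overlap_align(seqs[i], seqs[j])
            ca, cb = stats.coverage(len(seqs[i]), len(seqs[j]))
            ok = stats.columns > 0 and ca >= min_mutual_coverage and cb >= min_mutual_coverage
            valid[i, j] = valid[j, i] = ok
            d = 1.0 - stats.identity if stats.columns else 1.0
            dist[i, j] = dist[j, i] = d
    np.fill_diagonal(valid, True)

    keep = np.ones(n, bool)
    lengths = np.array([len(s) for s in seqs])
    while True:
        idx = np.where(keep)[0]
        if idx.size < 3:
            raise InsufficientDataError(
                f"fewer than 3 copies retained by the coverage filter ({idx.size})"
            )
        sub = valid[np.ix_(idx, idx)]
        bad = ~sub.all(axis=1)
        if not bad.any():
            break
        n_valid = sub.sum(axis=1)
        # drop the copy with fewest valid pairs; ties broken by shorter copy
        order = sorted(
            (int(n_valid[t]), int(lengths[idx[t]]), int(idx[t])) for t in np.where(bad)[0]
        )
        keep[order[0][2]] = False

    idx = np.where(keep)[0]
    return DistanceMatrix(
        labels=[labels[i] for i in idx],
        values=dist[np.ix_(idx, idx)],
        kept_mask=keep,
    )


@dataclass
class BurstReport:
    n_modes: int
    mode_means: list[float]  # ascending
    mode_weights: list[float]  # aligned with mode_means, summing to 1
    model_scores: dict[int, float]  # ICL per candidate component count


def _icl(gmm: GaussianMixture, X: np.ndarray) -> float:
    resp = gmm.predict_proba(X)
    with np.errstate(invalid="ignore"):
        ent = -np.sum(np.where(resp > 0, resp * np.log(np.clip(resp, 1e-300, None)), 0.0))
    return float(gmm.bic(X) + 2.0 * ent)


def detect_bursts(
    distances,
    margin: float = 10.0,
    max_modes: int = 3,
    seed: int = 0,
    n_restarts: int = 20,
    variance_floor: float = 1e-6,
) -> BurstReport:
    """Count expansion modes in a pairwise-distance distribution.

    Fits Gaussian mixtures with 1..max_modes components (deterministic
    quantile-spaced initialisation plus ``n_restarts`` seeded random
    restarts per count) and selects the count with the lowest ICL,
    requiring each more complex model to improve on the accepted simpler
    one by at least ``margin``.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    d = np.asarray(list(distances), dtype=float).ravel()
    if d.size < 30:
        raise InsufficientDataError(f"need >= 30 distance values (got {d.size})")
    X = d.reshape(-1, 1)
    scores: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    with warnings.catch_warnings():
        # near-constant inputs legitimately collapse components; the
        # variance floor handles them, so the fit warnings are noise here
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in range(1, max_modes + 1):
            q = np.quantile(d, np.linspace(0, 1, k + 2)[1:-1]).reshape(-1, 1)
            gq = GaussianMixture(
                n_components=k, means_init=q, reg_covar=variance_floor, random_state=0
            ).fit(X)
            best, best_score = gq, _icl(gq, X)
            gr = GaussianMixture(
                n_components=k,
                n_init=n_restarts,
                init_params="random",
                reg_covar=variance_floor,
                random_state=seed * 1000 + k,
            ).fit(X)
            s = _icl(gr, X)
            if s < best_score:
                best, best_score = gr, s
            scores[k] = best_score
            fits[k] = best
    selected = 1
    for k in range(2, max_modes + 1):
        if scores[k] < scores[selected] - margin:
            selected = k
    g = fits[selected]
    means = g.means_.ravel()
    order = np.argsort(means)
    return BurstReport(
        n_modes=selected,
        mode_means=[float(m) for m in means[order]],
        mode_weights=[float(w) for w in g.weights_[order]],
        model_scores=scores,
    )


_STOP_SPLIT = "*"


def _orf_fragments(seq: str, min_len_aa: int = 20) -> list[str]:
    """Six-frame translation split at stops into fragments >= min_len_aa."""
    from Bio.Seq import Seq

    frags: list[str] = []
    rc = str(Seq(seq).reverse_complement())
    for template in (seq, rc):
        for frame in range(3):
            sub = template[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            aa = str(Seq(sub).translate())
            frags.extend(f for f in aa.split(_STOP_SPLIT) if len(f) >= min_len_aa)
    return frags


def domain_retention(
    copies,
    domain_profiles: list[tuple[str, str]],
    score_fraction: float = 0.6,
    coverage_fraction: float = 0.6,
    min_fragment_aa: int = 20,
) -> dict[str, float]:
    """Fraction of copies retaining each protein domain.

    A copy retains a domain when any ORF fragment (six-frame translation,
    stops splitting frames, fragments >= ``min_fragment_aa``) aligns
    locally to the profile peptide with score >= ``score_fraction`` of the
    profile self-score over >= ``coverage_fraction`` of its length.
    """
    if not domain_profiles:
        raise InputError("domain profile list is empty")
    for label, pep in domain_profiles:
        if len(pep) < 20:
            raise InputError(f"domain profile '{label}' shorter than 20 aa")
    seqs, _ = _copy_seqs(copies)
    if not seqs:
        raise InputError("no copies given")
    aligner = make_protein_aligner()
    out: dict[str, float] = {}
    for label, pep in domain_profiles:
        self_score = float(aligner.align(pep, pep).score)
        need = score_fraction * self_score
        need_cov = coverage_fraction * len(pep)
        retained = 0
        for seq in seqs:
            hit = False
            for frag in _orf_fragments(seq, min_fragment_aa):
                alns = aligner.align(frag, pep)
                if alns.score < need:
                    continue
                aln = alns[0]
                blocks = aln.aligned[1]  # spans on the profile
                if len(blocks) == 0:
                    continue
                cov = int(blocks[-1][1]) - int(blocks[0][0])
                if cov >= need_cov:
                    hit = True
                    break
            retained += hit
        out[label] = retained / len(seqs)
    return out
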