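"""TPM normalisation and the tau tissue-specificity score.

Tau is defined as one minus the mean, over all tissues including the
maximal one, of each tissue's expression divided by the maximum:

    tau = 1 - (1/n) * sum_i x_i / max_j x_j

so a uniformly expressed gene scores 0 and a single-tissue gene scores
1 - 1/n, approaching 1 as the number of tissues grows. The common
variant that omits the maximal tissue and divides by n - 1 is available
as ``method="yanai"`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateColumnError, InputError, InsufficientDataError, UndefinedTauError


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from read counts and transcript lengths.

    rate_g = count_g / length_g per tissue; TPM_g = rate_g / sum(rates) * 1e6.
    Every output column sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise InputError(f"no length for gene '{missing}'")
    if (lengths <= 0).any():
        raise InputError("gene lengths must be positive")
    if (counts.values < 0).any():
        raise InputError("counts must be non-negative")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateColumnError(f"tissue '{zero.index[0]}' has zero total rate")
    return rates.div(totals, axis=1) * 1e6


def tau_score(expression, method: str = "mean_ratio") -> float:
    """Tissue-specificity tau of one gene's expression vector."""
    x = np.asarray(list(expression), dtype=float)
    if x.size < 2:
        raise InputError("tau needs at least 2 tissues")
    if (x < 0).any():
        raise InputError("expression must be non-negative")
    m = x.max()
    if m == 0:
        raise UndefinedTauError("tau undefined for an all-zero expression vector")
    ratios = x / m
    if method == "mean_ratio":
        return float(1.0 - ratios.mean())
    if method == "yanai":
        return float((1.0 - ratios).sum() / (x.size - 1))
    raise InputError(f"unknown tau method '{method}'")


@dataclass
class TauResult:
    tau: pd.Series  # gene -> tau in [0, 1]
    max_tissue: pd.Series  # gene -> argmax tissue
    excluded_genes: list[str] = field(default_factory=list)


def tau_table(
    expression: pd.DataFrame,
    min_tpm: float = 1.0,
    method: str = "mean_ratio",
    replicates: dict[str, list[str]] | None = None,
) -> TauResult:
    """Per-gene tau over an expression matrix (genes x tissues).

    Genes whose maximal expression is below ``min_tpm`` are excluded (a
    floor against noise-driven tau ~ 1 calls) and listed in
    ``excluded_genes``. If ``replicates`` maps tissue names to column
    lists, replicate columns are averaged per tissue first.
    """
    if replicates:
        expression = pd.DataFrame(
            {t: expression[cols].mean(axis=1) for t, cols in replicates.items()}
        )
    if expression.shape[1] < 2:
        raise InputError("need at least 2 tissues")
    vals = expression.values.astype(float)
    if (vals < 0).any():
        raise InputError("expression must be non-negative")
    maxima = vals.max(axis=1)
    keep = maxima >= min_tpm
    excluded = list(expression.index[~keep])
    kept = expression.loc[keep]
    if kept.shape[0]:
        ratios = kept.values / kept.values.max(axis=1, keepdims=True)
        if method == "mean_ratio":
            tau = 1.0 - ratios.mean(axis=1)
        elif method == "yanai":
            tau = (1.0 - ratios).sum(axis=1) / (kept.shape[1] - 1)
        else:
            raise InputError(f"unknown tau method '{method}'")
        max_tissue = kept.columns[np.argmax(kept.values, axis=1)]
    else:
        tau = np.array([])
        max_tissue = np.array([], dtype=object)
    return TauResult(
        tau=pd.Series(tau, index=kept.index, name="tau"),
        max_tissue=pd.Series(max_tissue, index=kept.index, name="max_tissue"),
        excluded_genes=excluded,
    )


def compare_tau_groups(tau_a, tau_b) -> dict[str, float]:
    """Two-sided rank-sum comparison of two tau distributions.

    Uses the Mann-Whitney U statistic with normal approximation and tie
    correction; reports group medians alongside.
    """
    a = np.asarray(list(tau_a), dtype=float)
    b = np.asarray(list(tau_b), dtype=float)
    if a.size < 5 or b.size < 5:
        raise InsufficientDataError("each group needs at least 5 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        # every observation tied: the statistic sits at its null mean
        return {
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "rank_statistic": a.size * b.size / 2.0,
            "p_value": 1.0,
        }
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "rank_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }
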