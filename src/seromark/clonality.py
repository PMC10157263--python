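"""Absolute kappa/lambda monoclonality scoring.

Monoclonal B-cell populations express a single immunoglobulin light chain,
skewing the kappa/lambda output ratio in either direction.  The absolute
kappa/lambda score quantifies that skew symmetrically:

    score = | log2( (kappa + eps) / (lambda + eps) ) |

with a small pseudocount eps guarding against zero abundances.  The score is
0 for balanced output, grows with restriction towards either chain, and is
invariant under swapping the chains.  Alternative monotone-equivalent
formulas (log10 ratio, max/min ratio) are available; every downstream use is
rank-based, so the choice does not affect test results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import RankTestResult, rank_sum_test, spearman

DEFAULT_PSEUDOCOUNT = 1e-3

_VARIANTS = ("log2", "log10", "maxmin")


def kappa_lambda_score(kappa, lambda_, pseudocount: float = DEFAULT_PSEUDOCOUNT, variant: str = "log2"):
    """Absolute light-chain restriction score of kappa vs lambda abundance.

    Vectorised over array input.  Raises on negative abundance or
    non-positive pseudocount.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    k = np.asarray(kappa, dtype=float)
    l = np.asarray(lambda_, dtype=float)
    if np.any(k < 0) or np.any(l < 0):
        raise ValueError("abundances must be non-negative")
    a = k + pseudocount
    b = l + pseudocount
    # written as |log(a) - log(b)| (and max/min) so the score is exactly
    # symmetric under swapping the chains, to the last floating-point bit
    if variant == "log2":
        out = np.abs(np.log2(a) - np.log2(b))
    elif variant == "log10":
        out = np.abs(np.log10(a) - np.log10(b))
    else:
        out = np.maximum(a, b) / np.minimum(a, b)
    if out.ndim == 0:
        return float(out)
    return out


def score_table(records: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT, variant: str = "log2") -> pd.DataFrame:
    """Append a ``score`` column to a kappa/lambda record table."""
    out = records.copy()
    out["score"] = kappa_lambda_score(out["kappa"], out["lambda_"], pseudocount, variant)
    return out


def compare_scores(scores_by_group: dict[str, np.ndarray], contrasts=None) -> pd.DataFrame:
    """Two-sided rank-sum comparison of scores between groups.

    ``contrasts`` is a list of (group_a, group_b) names; default is every
    group against every later group in mapping order.  Returns one row per
    contrast with the U statistic, p-value and group medians.
    """
    names = list(scores_by_group)
    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in contrasts:
        res: RankTestResult = rank_sum_test(scores_by_group[a], scores_by_group[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "median_a": res.median_a,
                "median_b": res.median_b,
                "n_a": res.n_a,
                "n_b": res.n_b,
            }
        )
    return pd.DataFrame(rows)


def score_cross_layer_correlation(
    transcript_scores: pd.Series,
    protein_scores: pd.Series,
    group_labels: pd.Series,
) -> pd.DataFrame:
    """Per-group Spearman correlation of the score across omics layers.

    Inputs are indexed by subject id; only subjects present in both layers
    (and the label series) enter.  Groups with fewer complete subjects than
    the correlation minimum are flagged undefined.
    """
    shared = transcript_scores.index.intersection(protein_scores.index).intersection(group_labels.index)
    return _per_group_correlation(
        transcript_scores.loc[shared], protein_scores.loc[shared], group_labels.loc[shared]
    )


def score_marker_correlation(
    scores: pd.Series,
    marker_abundance: pd.Series,
    group_labels: pd.Series,
) -> pd.DataFrame:
    """Per-group Spearman correlation of the serum score with a serum marker."""
    shared = scores.index.intersection(marker_abundance.index).intersection(group_labels.index)
    return _per_group_correlation(scores.loc[shared], marker_abundance.loc[shared], group_labels.loc[shared])


def _per_group_correlation(x: pd.Series, y: pd.Series, labels: pd.Series) -> pd.DataFrame:
    rows = []
    for group in pd.unique(labels):
        mask = labels == group
        rho, p, n = spearman(x[mask].to_numpy(), y[mask].to_numpy())
        rows.append({"group": group, "rho": rho, "p_value": p, "n": n, "defined": bool(np.isfinite(rho))})
    return pd.DataFrame(rows).set_index("group")
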