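"""Tumour-derived serum marker discovery from paired proteome/transcriptome.

A serum protein is called *tumour-derived* when it is (i) differentially
abundant between cases and controls in the serum proteome, (ii) its
transcript is concordantly differential in the tissue transcriptome, and
(iii) protein and transcript abundances are positively rank-correlated
across the subjects profiled in both layers — the signature of a protein the
tumour itself secretes into serum.

Per-layer differential expression uses a two-sided Wilcoxon rank-sum test on
library-size-normalised abundances with Benjamini-Hochberg FDR within the
layer; cross-layer association uses across-subject Spearman correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, PairedOmics
from .stats import MIN_N_CORRELATION, benjamini_hochberg, spearman_rowwise

log = logging.getLogger(__name__)


@dataclass
class SelectionThresholds:
    """Dual fold-change / significance thresholds for the intersection rule.

    Defaults: proteomic |log2FC| >= log2(1.2), transcriptomic |log2FC| >=
    log2(1.5), BH q < 0.05 in each layer, raw correlation p < 0.05 with
    rho > 0, and concordant fold-change direction across layers.
    """

    prot_log2fc_min: float = float(np.log2(1.2))
    trans_log2fc_min: float = float(np.log2(1.5))
    alpha_de: float = 0.05
    alpha_corr: float = 0.05
    require_concordant_direction: bool = True
    adjust_correlation: bool = False

    def __post_init__(self) -> None:
        if self.prot_log2fc_min <= 0 or self.trans_log2fc_min <= 0:
            raise ValueError("fold-change thresholds must be > 0")
        for a in (self.alpha_de, self.alpha_corr):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha levels must lie in (0, 1)")


def normalize_library_size(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each subject column to the mean total abundance of the layer."""
    totals = matrix.values.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("subject with all-zero abundances cannot be normalized")
    scaled = matrix.values * (totals.mean() / totals)
    return ExpressionMatrix(matrix.layer, matrix.feature_ids, matrix.subject_ids, scaled)


def default_pseudocount(matrix: ExpressionMatrix) -> float:
    """Half the smallest nonzero abundance of the layer (zero-handling)."""
    nz = matrix.values[matrix.values > 0]
    if nz.size == 0:
        return 0.5
    return float(nz.min() / 2.0)


def differential_expression(
    matrix: ExpressionMatrix,
    case_ids,
    control_ids,
    pseudocount: float | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-feature case-vs-control differential expression for one layer.

    Returns a frame indexed like ``matrix.feature_ids`` with columns
    ``log2fc`` (mean log2(x + pseudocount) difference, case minus control),
    ``p_value`` (two-sided Wilcoxon rank-sum) and ``q_value`` (BH within
    the layer).  Features with zero variance across both groups get p = 1.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control ids overlap")
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("need at least two subjects per group")
    if normalize:
        matrix = normalize_library_size(matrix)
    if pseudocount is None:
        pseudocount = default_pseudocount(matrix)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    X = matrix.subject_columns(case_ids)
    Y = matrix.subject_columns(control_ids)
    log2fc = np.log2(X + pseudocount).mean(axis=1) - np.log2(Y + pseudocount).mean(axis=1)
    res = stats.mannwhitneyu(X, Y, alternative="two-sided", axis=1, method="asymptotic")
    p = np.asarray(res.pvalue, float)
    flat = np.ptp(np.concatenate([X, Y], axis=1), axis=1) == 0
    p[flat] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = benjamini_hochberg(p)
    return pd.DataFrame(
        {"feature_id": matrix.feature_ids, "log2fc": log2fc, "p_value": p, "q_value": q}
    ).set_index("feature_id")


def pair_correlation(paired: PairedOmics, min_n: int = MIN_N_CORRELATION) -> pd.DataFrame:
    """Across-subject Spearman correlation for every protein-mRNA pair.

    Computed over the subjects profiled in both layers (average-rank tie
    handling; two-sided p from the t-approximation).  Pairs with fewer than
    ``min_n`` complete observations are emitted with ``rho`` undefined and
    ``defined = False``.
    """
    shared = paired.shared_subjects
    if len(shared) == 0:
        raise ValueError("no shared subjects between layers")
    P = paired.proteome.subject_columns(shared)
    T = paired.transcriptome.subject_columns(shared)
    prot_rows = [paired.proteome._findex[p] for p, _, _ in paired.pair_map]
    trans_rows = [paired.transcriptome._findex[t] for _, t, _ in paired.pair_map]
    X = P[prot_rows]
    Y = T[trans_rows]
    complete = (np.isfinite(X) & np.isfinite(Y)).sum(axis=1)
    rho, p = spearman_rowwise(X, Y)
    defined = complete >= min_n
    rho = np.where(defined, rho, np.nan)
    p = np.where(defined, p, np.nan)
    return pd.DataFrame(
        {
            "gene_symbol": paired.gene_symbols,
            "rho": rho,
            "p_value": p,
            "n_subjects": complete,
            "defined": defined,
        }
    ).set_index("gene_symbol")


def select_tumour_derived(
    de_prot: pd.DataFrame,
    de_trans: pd.DataFrame,
    corrs: pd.DataFrame,
    thresholds: SelectionThresholds | None = None,
    pair_map=None,
) -> pd.DataFrame:
    """Intersect the three evidence tables into the tumour-derived candidate set.

    A gene is selected when it is positively and significantly correlated
    across layers AND passes the dual fold-change/FDR criteria in both
    layers AND (by default) is dysregulated in the same direction in both.
    The returned frame carries one boolean column per criterion (the
    per-gene rationale) and ``selected``.

    ``de_prot``/``de_trans`` may be indexed by layer feature ids if
    ``pair_map`` is given to translate them to gene symbols.
    """
    thr = thresholds or SelectionThresholds()
    if pair_map is not None:
        prot_to_gene = {p: g for p, _, g in pair_map}
        trans_to_gene = {t: g for _, t, g in pair_map}
        de_prot = de_prot.rename(index=prot_to_gene)
        de_trans = de_trans.rename(index=trans_to_gene)
    rows = []
    corr_p = corrs["p_value"]
    if thr.adjust_correlation:
        ok = corrs["defined"] if "defined" in corrs else corr_p.notna()
        adj = pd.Series(np.nan, index=corrs.index)
        adj[ok] = benjamini_hochberg(corr_p[ok].to_numpy())
        corr_p = adj
    for gene in corrs.index:
        if gene not in de_prot.index or gene not in de_trans.index:
            log.warning("gene %s present in correlations but missing a DE table; excluded", gene)
            continue
        rho = corrs.at[gene, "rho"]
        pc = corr_p.loc[gene]
        lfc_p, q_p = de_prot.at[gene, "log2fc"], de_prot.at[gene, "q_value"]
        lfc_t, q_t = de_trans.at[gene, "log2fc"], de_trans.at[gene, "q_value"]
        pass_corr = bool(np.isfinite(rho) and rho > 0 and pc < thr.alpha_corr)
        pass_prot = bool(abs(lfc_p) >= thr.prot_log2fc_min and q_p < thr.alpha_de)
        pass_trans = bool(abs(lfc_t) >= thr.trans_log2fc_min and q_t < thr.alpha_de)
        pass_dir = bool(np.sign(lfc_p) == np.sign(lfc_t)) or not thr.require_concordant_direction
        rows.append(
            {
                "gene_symbol": gene,
                "rho": rho,
                "corr_p": pc,
                "log2fc_prot": lfc_p,
                "q_prot": q_p,
                "log2fc_trans": lfc_t,
                "q_trans": q_t,
                "pass_correlation": pass_corr,
                "pass_prot_de": pass_prot,
                "pass_trans_de": pass_trans,
                "pass_direction": pass_dir,
                "selected": pass_corr and pass_prot and pass_trans and pass_dir,
            }
        )
    return pd.DataFrame(rows).set_index("gene_symbol")


def isotype_panel_summary(
    de_prot: pd.DataFrame,
    de_trans: pd.DataFrame,
    corrs: pd.DataFrame,
    isotype_genes,
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict the DE and correlation tables to an immunoglobulin panel.

    Returns (table, missing): a heatmap-ready per-isotype summary joining
    both layers' fold changes/q-values and the cross-layer correlation, plus
    the panel members absent from the results (listed, not fatal).  No new
    statistics are computed.
    """
    present, missing = [], []
    for g in isotype_genes:
        if g in corrs.index and g in de_prot.index and g in de_trans.index:
            present.append(g)
        else:
            missing.append(g)
    table = pd.DataFrame(
        {
            "log2fc_prot": de_prot.loc[present, "log2fc"],
            "q_prot": de_prot.loc[present, "q_value"],
            "log2fc_trans": de_trans.loc[present, "log2fc"],
            "q_trans": de_trans.loc[present, "q_value"],
            "rho": corrs.loc[present, "rho"],
            "corr_p": corrs.loc[present, "p_value"],
        },
        index=pd.Index(present, name="gene_symbol"),
    )
    return table, missing
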