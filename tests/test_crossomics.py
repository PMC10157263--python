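"""Cross-omics discovery: DE, Spearman correlation and intersection selection,
each pinned against an independent small-n oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

import seromark as sm
from seromark.containers import ExpressionMatrix, PairedOmics
from seromark.crossomics import (
    SelectionThresholds,
    differential_expression,
    isotype_panel_summary,
    pair_correlation,
    select_tumour_derived,
)
from seromark.stats import rank_sum_test


def _matrix(values, layer="proteome", prefix="F"):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        layer,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"S{j}" for j in range(values.shape[1])],
        values,
    )


def test_exact_doubling_gives_unit_log2fc():
    base = np.abs(np.random.default_rng(0).normal(10, 2, size=(5, 4))) + 1
    values = np.concatenate([2 * base, base], axis=1)
    m = ExpressionMatrix("proteome", [f"F{i}" for i in range(5)],
                         [f"C{j}" for j in range(4)] + [f"K{j}" for j in range(4)], values)
    de = differential_expression(m, [f"C{j}" for j in range(4)], [f"K{j}" for j in range(4)],
                                 pseudocount=1e-12, normalize=False)
    np.testing.assert_allclose(de["log2fc"], 1.0, atol=1e-9)


def test_zero_variance_feature_gets_p_one():
    values = np.ones((3, 8))
    values[1] = np.arange(8) + 1.0
    m = _matrix(values)
    de = differential_expression(m, ["S0", "S1", "S2", "S3"], ["S4", "S5", "S6", "S7"], normalize=False)
    assert de["p_value"].iloc[0] == 1.0
    assert de["p_value"].iloc[2] == 1.0
    assert de["p_value"].iloc[1] < 1.0


def test_unknown_subject_id_errors(small_omics):
    with pytest.raises(KeyError):
        differential_expression(small_omics.paired.proteome, ["nope", "nope2"], small_omics.prot_control_ids)


def test_bh_q_values_monotone_and_dominate_p(small_omics):
    de = differential_expression(small_omics.paired.proteome,
                                 small_omics.prot_case_ids, small_omics.prot_control_ids)
    assert (de["q_value"] >= de["p_value"] - 1e-12).all()
    q_sorted = de.sort_values("p_value")["q_value"].to_numpy()
    assert np.all(np.diff(q_sorted) >= -1e-12)


def test_rank_sum_p_matches_exhaustive_permutation_oracle(rng):
    """At n<=6 per group the rank-sum p equals full permutation enumeration."""
    for n_a, n_b in [(4, 4), (5, 6), (6, 5)]:
        x = rng.normal(size=n_a)
        y = rng.normal(size=n_b) + 0.5
        res = rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        obs = ranks[:n_a].sum()
        total = 0
        extreme = 0
        mean_r = n_a * (len(pooled) + 1) / 2.0
        for comb in itertools.combinations(range(len(pooled)), n_a):
            total += 1
            if abs(ranks[list(comb)].sum() - mean_r) >= abs(obs - mean_r) - 1e-9:
                extreme += 1
        assert res.p_value == pytest.approx(extreme / total, abs=1e-12)


def test_spearman_matches_rank_construction_oracle_over_permutations():
    """rho at n=5 equals Pearson on explicitly constructed average ranks, all 120 orders."""
    x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])  # includes a tie
    prot = _matrix(x[None, :], "proteome", "P")
    for perm in itertools.permutations(range(5)):
        y = np.array([10.0, 20.0, 20.0, 30.0, 40.0])[list(perm)]
        trans = _matrix(y[None, :], "transcriptome", "T")
        paired = PairedOmics(prot, trans, [("P0", "T0", "G")], [f"S{j}" for j in range(5)])
        rho = pair_correlation(paired)["rho"].iloc[0]

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


def test_correlation_invariant_to_monotone_transform(small_omics):
    paired = small_omics.paired
    transformed = ExpressionMatrix(
        "transcriptome",
        paired.transcriptome.feature_ids,
        paired.transcriptome.subject_ids,
        np.expm1(np.log1p(paired.transcriptome.values) * 1.7),
    )
    a = pair_correlation(paired)["rho"]
    b = pair_correlation(PairedOmics(paired.proteome, transformed, paired.pair_map, paired.shared_subjects))["rho"]
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_perfect_monotone_pair_gives_rho_one():
    x = np.array([[1.0, 5.0, 2.0, 9.0, 4.0, 7.0]])
    prot = _matrix(x, "proteome", "P")
    trans = _matrix(np.exp(x / 3.0), "transcriptome", "T")
    paired = PairedOmics(prot, trans, [("P0", "T0", "G")], [f"S{j}" for j in range(6)])
    assert pair_correlation(paired)["rho"].iloc[0] == pytest.approx(1.0)


def test_pairs_below_min_n_flagged_undefined():
    x = np.array([[1.0, 2.0, 3.0, 4.0]])
    prot = _matrix(x, "proteome", "P")
    trans = _matrix(x * 2, "transcriptome", "T")
    paired = PairedOmics(prot, trans, [("P0", "T0", "G")], [f"S{j}" for j in range(4)])
    out = pair_correlation(paired)
    assert not out["defined"].iloc[0]
    assert np.isnan(out["rho"].iloc[0])
    with pytest.raises(ValueError):
        pair_correlation(PairedOmics(prot, trans, [("P0", "T0", "G")], []))


def _discovery(sim):
    de_p = differential_expression(sim.paired.proteome, sim.prot_case_ids, sim.prot_control_ids)
    de_t = differential_expression(sim.paired.transcriptome, sim.trans_case_ids, sim.trans_control_ids)
    corrs = pair_correlation(sim.paired)
    return de_p, de_t, corrs


def test_planted_marker_selected(small_omics):
    de_p, de_t, corrs = _discovery(small_omics)
    sel = select_tumour_derived(de_p, de_t, corrs, pair_map=small_omics.paired.pair_map)
    assert sel.loc["GENE0001", "selected"]


def test_selection_monotone_in_thresholds(small_omics):
    """Relaxing any threshold never removes a candidate."""
    de_p, de_t, corrs = _discovery(small_omics)
    strict = SelectionThresholds()
    loose = SelectionThresholds(prot_log2fc_min=0.05, trans_log2fc_min=0.05, alpha_de=0.2, alpha_corr=0.2)
    s1 = select_tumour_derived(de_p, de_t, corrs, strict, small_omics.paired.pair_map)
    s2 = select_tumour_derived(de_p, de_t, corrs, loose, small_omics.paired.pair_map)
    strict_set = set(s1.index[s1["selected"]])
    loose_set = set(s2.index[s2["selected"]])
    assert strict_set <= loose_set


def test_infinite_thresholds_select_nothing(small_omics):
    de_p, de_t, corrs = _discovery(small_omics)
    thr = SelectionThresholds(prot_log2fc_min=1e9, trans_log2fc_min=1e9)
    sel = select_tumour_derived(de_p, de_t, corrs, thr, small_omics.paired.pair_map)
    assert not sel["selected"].any()


def test_gene_missing_from_de_table_excluded_with_warning(small_omics, caplog):
    de_p, de_t, corrs = _discovery(small_omics)
    de_p2 = de_p.rename(index={p: g for p, _, g in small_omics.paired.pair_map}).drop(index="GENE0002")
    de_t2 = de_t.rename(index={t: g for _, t, g in small_omics.paired.pair_map})
    with caplog.at_level("WARNING"):
        sel = select_tumour_derived(de_p2, de_t2, corrs)
    assert "GENE0002" not in sel.index
    assert any("GENE0002" in rec.message for rec in caplog.records)


def test_isotype_panel_restriction_consistency(small_omics):
    de_p, de_t, corrs = _discovery(small_omics)
    de_p = de_p.rename(index={p: g for p, _, g in small_omics.paired.pair_map})
    de_t = de_t.rename(index={t: g for _, t, g in small_omics.paired.pair_map})
    table, missing = isotype_panel_summary(de_p, de_t, corrs, ["GENE0001", "GENE0002", "NOT_A_GENE"])
    assert list(table.index) == ["GENE0001", "GENE0002"]
    assert missing == ["NOT_A_GENE"]
    assert table.loc["GENE0001", "log2fc_prot"] == de_p.loc["GENE0001", "log2fc"]
    empty, _ = isotype_panel_summary(de_p, de_t, corrs, [])
    assert empty.empty


def test_only_planted_isotype_passes_selection():
    cfg = sm.OmicsSimConfig(n_pairs=150, n_planted=1, planted_symbols=["IGHM"], seed=19)
    sim = sm.generate_paired_omics(cfg)
    de_p, de_t, corrs = _discovery(sim)
    sel = select_tumour_derived(de_p, de_t, corrs, pair_map=sim.paired.pair_map)
    panel = ["IGHM", "GENE0002", "GENE0003", "GENE0004"]
    winners = [g for g in panel if g in sel.index and sel.loc[g, "selected"]]
    assert winners == ["IGHM"]
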