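"""Generator contracts: determinism, planted structure, null behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import seromark as sm
from seromark.simulate import config_from_yaml, config_to_yaml, generate_clonality_paired
from seromark.stats import spearman


def test_paired_omics_dimensions_and_planted_ids(small_omics):
    paired = small_omics.paired
    assert paired.proteome.shape == (200, 28 + 30)
    assert paired.transcriptome.shape == (200, 38 + 31)
    assert len(paired.pair_map) == 200
    assert small_omics.planted_genes == ["GENE0001"]
    assert np.all(paired.proteome.values > 0)
    assert np.all(paired.transcriptome.values > 0)


def test_generation_is_deterministic():
    cfg = sm.OmicsSimConfig(n_pairs=50, seed=42)
    a = sm.generate_paired_omics(cfg)
    b = sm.generate_paired_omics(cfg)
    np.testing.assert_array_equal(a.paired.proteome.values, b.paired.proteome.values)
    np.testing.assert_array_equal(a.paired.transcriptome.values, b.paired.transcriptome.values)
    coh_cfg = sm.CohortSimConfig(n_per_class=(10, 5, 5, 10), seed=42)
    pd.testing.assert_frame_equal(sm.generate_cohort(coh_cfg), sm.generate_cohort(coh_cfg))
    cl_cfg = sm.ClonalitySimConfig(seed=42)
    pd.testing.assert_frame_equal(generate_clonality_paired(cl_cfg)[0], generate_clonality_paired(cl_cfg)[0])


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        sm.OmicsSimConfig(shared_subject_fraction=0.0)
    with pytest.raises(ValueError):
        sm.OmicsSimConfig(n_planted=10, n_pairs=5)
    with pytest.raises(ValueError):
        sm.OmicsSimConfig(cross_omics_rho=1.5)
    with pytest.raises(ValueError):
        sm.CohortSimConfig(n_per_class=(0, 0, 0, 0))
    with pytest.raises(ValueError):
        sm.ClonalitySimConfig(restriction=0.3)


def test_planted_log2fc_recovered_over_seeds():
    """Monte-Carlo: empirical log2FC of the planted marker is centred on the config value."""
    target = 2.64
    ests = []
    for seed in range(40):
        cfg = sm.OmicsSimConfig(n_pairs=10, noise_sd=0.8, planted_log2fc_prot=target, seed=seed)
        sim = sm.generate_paired_omics(cfg)
        prot = sim.paired.proteome
        log2 = np.log2(prot.values)
        cases = [prot._sindex[s] for s in sim.prot_case_ids]
        ctrls = [prot._sindex[s] for s in sim.prot_control_ids]
        ests.append(log2[0, cases].mean() - log2[0, ctrls].mean())
    ests = np.asarray(ests)
    se = ests.std(ddof=1) / np.sqrt(ests.size)
    assert abs(ests.mean() - target) < 3 * se + 1e-9


def test_planted_cross_layer_correlation_targets_rho():
    """With zero fold change the planted pair's Spearman rho approaches the config target."""
    rhos = []
    for seed in range(30):
        cfg = sm.OmicsSimConfig(
            n_pairs=5, planted_log2fc_prot=0.0, planted_log2fc_trans=0.0,
            cross_omics_rho=0.6, shared_subject_fraction=1.0, seed=seed,
        )
        sim = sm.generate_paired_omics(cfg)
        from seromark.crossomics import pair_correlation

        rhos.append(pair_correlation(sim.paired)["rho"].iloc[0])
    assert abs(np.mean(rhos) - 0.6) < 0.1


def test_null_omics_gives_nominal_false_positive_rate():
    """All effects at null: ~alpha of pairs reach p<0.05 in DE and correlation."""
    cfg = sm.OmicsSimConfig(
        n_pairs=1000, n_planted=0, cross_omics_rho=0.0,
        planted_log2fc_prot=0.0, planted_log2fc_trans=0.0, seed=5,
    )
    sim = sm.generate_paired_omics(cfg)
    from seromark.crossomics import differential_expression, pair_correlation

    de = differential_expression(sim.paired.proteome, sim.prot_case_ids, sim.prot_control_ids)
    frac_de = (de["p_value"] < 0.05).mean()
    corr = pair_correlation(sim.paired)
    frac_corr = (corr["p_value"] < 0.05).mean()
    # binomial 3-sigma band around 0.05 at n=1000 is roughly +-0.02
    assert 0.02 < frac_de < 0.08
    assert 0.02 < frac_corr < 0.08


def test_cohort_counts_and_columns(cohort205):
    assert len(cohort205) == 205
    counts = cohort205["diagnosis_class"].value_counts()
    assert counts["EMZL"] == 68 and counts["chronic_inflammation"] == 78
    for col in ("sex", "date_of_diagnosis", "bilateral", "disease_site", "lacrimal_involvement"):
        assert col in cohort205.columns
    assert cohort205.loc[cohort205["diagnosis_class"] == "EMZL", "igm_post_treatment"].notna().all()
    assert (cohort205["igm_g_per_l"] > 0).all()


def test_zero_age_slope_gives_null_age_correlation():
    rhos = []
    for seed in range(25):
        cfg = sm.CohortSimConfig(n_per_class=(0, 0, 0, 80), age_igm_slope_controls=0.0, seed=seed)
        coh = sm.generate_cohort(cfg)
        rho, _, _ = spearman(coh["igm_g_per_l"], coh["age_years"])
        rhos.append(rho)
    assert abs(np.mean(rhos)) < 0.07


def test_negative_age_slope_shows_in_controls_not_cases():
    cfg = sm.CohortSimConfig(n_per_class=(150, 0, 0, 150), age_igm_slope_controls=-0.02, seed=3)
    coh = sm.generate_cohort(cfg)
    ctrl = coh[coh["diagnosis_class"] == "chronic_inflammation"]
    case = coh[coh["diagnosis_class"] == "EMZL"]
    rho_c, p_c, _ = spearman(ctrl["igm_g_per_l"], ctrl["age_years"])
    rho_e, _, _ = spearman(case["igm_g_per_l"], case["age_years"])
    assert rho_c < -0.2 and p_c < 0.01
    assert abs(rho_e) < 0.2


def test_treatment_effect_self_consistent():
    """Mean post-minus-pre IgM in cases matches treatment_effect within MC error."""
    deltas = []
    for seed in range(60):
        cfg = sm.CohortSimConfig(
            n_per_class=(100, 0, 0, 1), igm_log_mean_case=np.log(3.0),
            igm_log_sd=0.3, treatment_effect=-0.5, seed=seed,
        )
        coh = sm.generate_cohort(cfg)
        cases = coh[coh["diagnosis_class"] == "EMZL"]
        deltas.append((cases["igm_post_treatment"] - cases["igm_g_per_l"]).mean())
    deltas = np.asarray(deltas)
    se = deltas.std(ddof=1) / np.sqrt(deltas.size)
    assert abs(deltas.mean() + 0.5) < 3 * se + 1e-9


def test_clonality_null_restriction_indistinguishable():
    from seromark.clonality import score_table
    from seromark.stats import rank_sum_test

    ps = []
    for seed in range(20):
        cfg = sm.ClonalitySimConfig(restriction=0.5, seed=seed)
        scored = score_table(sm.generate_clonality(cfg))
        ps.append(rank_sum_test(
            scored.loc[scored["group"] == "case", "score"],
            scored.loc[scored["group"] == "control", "score"],
        ).p_value)
    # null p-values should not pile up at small values
    assert np.mean(np.array(ps) < 0.05) <= 0.25


def test_clonality_full_restriction_degenerate_limit():
    from seromark.clonality import kappa_lambda_score

    cfg = sm.ClonalitySimConfig(restriction=1.0, n_cases=20, n_controls=1, seed=0)
    df = sm.generate_clonality(cfg)
    cases = df[df["group"] == "case"]
    eps = 1e-3
    for _, row in cases.iterrows():
        total = row["kappa"] + row["lambda_"]
        expected = abs(np.log2(eps / (total + eps)))
        assert kappa_lambda_score(row["kappa"], row["lambda_"], eps) == pytest.approx(expected)


def test_effect_monotonicity_in_restriction():
    """Median case score increases across a restriction grid (20 seeds per point)."""
    from seromark.clonality import score_table

    medians = []
    for restriction in (0.6, 0.75, 0.9):
        vals = []
        for seed in range(20):
            cfg = sm.ClonalitySimConfig(restriction=restriction, seed=seed)
            scored = score_table(sm.generate_clonality(cfg))
            vals.append(scored.loc[scored["group"] == "case", "score"].median())
        medians.append(np.mean(vals))
    assert medians[0] < medians[1] < medians[2]


def test_config_yaml_round_trip(tmp_path):
    cfg = sm.OmicsSimConfig(n_pairs=77, seed=9, planted_symbols=["IGHM"])
    path = tmp_path / "omics.yaml"
    config_to_yaml(cfg, path)
    assert config_from_yaml(path) == cfg
    coh = sm.CohortSimConfig(n_per_class=(1, 2, 3, 4), seed=5)
    assert config_from_yaml(config_to_yaml(coh)) == coh
    with pytest.raises(ValueError, match="unknown config key"):
        config_from_yaml("kind: clonality\nnot_a_field: 3\n")
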