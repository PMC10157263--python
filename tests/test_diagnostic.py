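"""Diagnostic model: selection, nomogram equivalence, split, calibration,
and the descriptive cohort analyses with their exact small-n oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import seromark as sm
from seromark.diagnostic import (
    age_cutoff,
    build_nomogram,
    calibration_assess,
    confounder_screen,
    delta_igm_analysis,
    group_tests,
    select_model,
    split_and_validate,
    stratified_split,
)
from seromark.logistic import fit_logistic


def _expit(x):
    return 1 / (1 + np.exp(-x))


def _synthetic_design(rng, n=2000, beta=(-1.5, 1.0, 2.2, 0.9)):
    mid = rng.binomial(1, 0.3, n).astype(float)
    high = np.where(mid == 1, 0.0, rng.binomial(1, 0.3, n)).astype(float)
    age = rng.binomial(1, 0.4, n).astype(float)
    X = pd.DataFrame({"intercept": np.ones(n), "igm_mid": mid, "igm_high": high, "age_lt_cutoff": age})
    eta = X.to_numpy() @ np.asarray(beta)
    y = (rng.random(n) < _expit(eta)).astype(float)
    return X, y


def test_select_model_empty_candidates_is_plain_fit(rng):
    X, y = _synthetic_design(rng, n=500)
    fit, report = select_model(X, pd.DataFrame(index=X.index), y)
    ref = fit_logistic(X, y)
    np.testing.assert_array_equal(fit.params, ref.params)
    assert report.empty


def test_select_model_includes_strong_and_orders_deterministically(rng):
    X, y0 = _synthetic_design(rng, n=1500)
    strong = rng.binomial(1, 0.5, len(X)).astype(float)
    eta = X.to_numpy() @ np.array([-1.5, 1.0, 2.2, 0.9]) + 1.8 * strong
    y = (rng.random(len(X)) < _expit(eta)).astype(float)
    cands = pd.DataFrame({"noise": rng.binomial(1, 0.5, len(X)).astype(float), "strong": strong})
    fit, report = select_model(X, cands, y)
    assert report.loc[report["candidate"] == "strong", "included"].item()
    assert "strong" in fit.terms


def test_null_candidate_inclusion_rate_matches_aic_theory():
    """A zero-effect candidate lowers AIC iff its LRT chi2 exceeds 2 (~16%)."""
    rng = np.random.default_rng(31)
    included = 0
    reps = 120
    for _ in range(reps):
        X, y = _synthetic_design(rng, n=400)
        cands = pd.DataFrame({"noise": rng.binomial(1, 0.5, len(X)).astype(float)})
        _, report = select_model(X, cands, y)
        included += int(report["included"].iloc[0])
    rate = included / reps
    assert 0.06 < rate < 0.28  # ~15.7% +- binomial noise


def test_nomogram_probability_equals_model_probability(rng):
    X, y = _synthetic_design(rng, n=1200)
    fit = fit_logistic(X, y)
    groups = {
        "igm_level": {"low": {}, "mid": {"igm_mid": 1.0}, "high": {"igm_high": 1.0}},
        "age_lt_cutoff": {"no": {}, "yes": {"age_lt_cutoff": 1.0}},
    }
    nomo = build_nomogram(fit, groups)
    for igm_lvl, igm_cols in groups["igm_level"].items():
        for age_lvl, age_cols in groups["age_lt_cutoff"].items():
            row = np.array([
                1.0,
                igm_cols.get("igm_mid", 0.0),
                igm_cols.get("igm_high", 0.0),
                age_cols.get("age_lt_cutoff", 0.0),
            ])
            direct = float(fit.predict(row[None, :])[0])
            via_points = nomo.predict({"igm_level": igm_lvl, "age_lt_cutoff": age_lvl})
            assert via_points == pytest.approx(direct, abs=1e-9)


def test_nomogram_single_binary_predictor_scaling(rng):
    n = 400
    x = rng.binomial(1, 0.5, n).astype(float)
    y = (rng.random(n) < _expit(-1 + 2 * x)).astype(float)
    fit = fit_logistic(pd.DataFrame({"intercept": np.ones(n), "x": x}), y)
    nomo = build_nomogram(fit)
    pts = nomo.points["x"]
    assert sorted(pts.values()) == [0.0, 100.0]
    assert nomo.probability(100.0) == pytest.approx(_expit(fit.coef("intercept") + fit.coef("x")), abs=1e-12)


def test_nomogram_largest_range_gets_100_points(rng):
    X, y = _synthetic_design(rng, n=2000, beta=(-1.0, 0.5, 2.5, 1.0))
    fit = fit_logistic(X, y)
    nomo = build_nomogram(fit)
    ranges = {p: max(v.values()) - min(v.values()) for p, v in nomo.points.items()}
    assert max(ranges, key=ranges.get) == "igm_high"
    assert max(ranges.values()) == pytest.approx(100.0)


def test_stratified_split_preserves_class_proportions(cohort205):
    deriv, valid = stratified_split(cohort205, 0.6, seed=4)
    assert len(deriv) + len(valid) == len(cohort205)
    for cls, total in cohort205["diagnosis_class"].value_counts().items():
        got = (deriv["diagnosis_class"] == cls).sum()
        assert abs(got - 0.6 * total) <= 1.0
    # deterministic under the same seed
    deriv2, _ = stratified_split(cohort205, 0.6, seed=4)
    assert list(deriv["subject_id"]) == list(deriv2["subject_id"])


def test_split_fraction_one_flags_empty_validation(cohort205):
    sv = split_and_validate(cohort205, derivation_fraction=1.0, seed=0, n_boot=0)
    assert sv.validation_empty
    assert len(sv.validation) == 0


def test_model_score_beats_ordinal_marker_on_derivation():
    """With real lacrimal/age effects the combined model should dominate the
    ordinal marker alone on the derivation data in most seeds."""
    wins = 0
    for seed in range(15):
        coh = sm.generate_cohort(sm.CohortSimConfig(seed=seed))
        sv = split_and_validate(coh, seed=seed, n_boot=0)
        t = sv.roc_table
        d = t[t["set"] == "derivation"].set_index("score")["auc"]
        wins += d["model"] >= d["ordinal_marker"]
    assert wins >= 13


def test_diagnostic_results_summary_and_predict(cohort205):
    res = sm.DiagnosticModel(cohort205, n_boot=100).fit(seed=1)
    text = res.summary()
    assert "Youden cutoff" in text and "minimal-AIC cutoff" in text
    probs = res.predict(cohort205)
    assert probs.shape == (205,)
    assert np.all((probs > 0) & (probs < 1))
    lo, hi = res.cutoffs.boundaries
    assert lo < hi
    assert res.match is not None and len(res.match.pairs) > 0


def test_calibration_single_bin_reproduces_prevalence(rng):
    X, y = _synthetic_design(rng, n=400)
    fit = fit_logistic(X, y)
    tab = calibration_assess(fit, X, y, n_bins=1)
    assert len(tab) == 1
    assert tab["observed"].iloc[0] == pytest.approx(y.mean(), abs=1e-12)


def test_calibration_well_specified_model_close(rng):
    X, y = _synthetic_design(rng, n=2000)
    fit = fit_logistic(X, y)
    tab = calibration_assess(fit, X, y, n_bins=5, bootstrap_reps=30, seed=0)
    assert (tab["observed"] - tab["mean_predicted"]).abs().max() < 0.08
    assert "observed_corrected" in tab


def test_calibration_detects_shifted_probabilities(rng):
    X, y = _synthetic_design(rng, n=2000)
    fit = fit_logistic(X, y)
    shifted = fit
    shifted = type(fit)(terms=fit.terms, params=fit.params + np.array([1.0, 0, 0, 0]),
                        bse=fit.bse, log_likelihood=fit.log_likelihood, converged=True)
    tab = calibration_assess(shifted, X, y, n_bins=5)
    assert (tab["observed"] - tab["mean_predicted"]).mean() < -0.1


# --- descriptive analyses -----------------------------------------------------


def test_group_tests_emzl_higher_igm(cohort205):
    out = group_tests(cohort205)
    assert (out["median_a"] > out["median_b"]).all()
    assert (out["p_value"] < 0.01).all()
    assert (out["q_value"] >= out["p_value"] - 1e-12).all()


def test_delta_igm_zero_change_gives_p_one(cohort205):
    coh = cohort205.copy()
    coh["igm_post_treatment"] = np.where(
        coh["igm_post_treatment"].notna(), coh["igm_g_per_l"], np.nan
    )
    per, _ = delta_igm_analysis(coh)
    emzl = per[per["group"] == "EMZL"]
    assert emzl["p_value"].iloc[0] == 1.0
    assert emzl["median_delta"].iloc[0] == 0.0


def test_delta_igm_detects_treatment_decrease(cohort205):
    per, _ = delta_igm_analysis(cohort205)
    emzl = per[per["group"] == "EMZL"]
    assert emzl["median_delta"].iloc[0] < 0
    assert emzl["p_value"].iloc[0] < 0.001


def test_signed_rank_matches_exhaustive_enumeration(rng):
    """At n<=10 pairs, the signed-rank p equals enumeration over sign flips."""
    from seromark.stats import signed_rank_test

    for n in (6, 8, 10):
        d = rng.normal(0.3, 1.0, size=n)
        while np.any(d == 0):
            d = rng.normal(0.3, 1.0, size=n)
        _, p = signed_rank_test(d)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        total = w_obs_count = 0
        mean_w = ranks.sum() / 2.0
        for signs in itertools.product([0, 1], repeat=n):
            w = ranks[np.array(signs, bool)].sum()
            total += 1
            w_obs_count += abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9
        assert p == pytest.approx(w_obs_count / total, abs=1e-12)


def test_confounder_screen_recovers_negative_age_trend(cohort205):
    age_tab, sex_tab = confounder_screen(cohort205)
    ctrl = age_tab[age_tab["group"] == "controls"].iloc[0]
    emzl = age_tab[age_tab["group"] == "EMZL"].iloc[0]
    assert ctrl["rho"] < 0 and ctrl["p_value"] < 0.05
    assert abs(emzl["rho"]) < 0.35
    assert set(sex_tab.columns) == {"group", "statistic", "p_value"}


def test_age_cutoff_direction_and_range(cohort205):
    cut, auc = age_cutoff(cohort205)
    assert 25 < cut < 80
    assert auc > 0.5  # younger age predicts EMZL under the study conditions
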