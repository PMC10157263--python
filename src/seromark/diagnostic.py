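"""Case-control diagnostic modelling of a serum marker.

Ties the threshold-finding toolkit together into a preoperative diagnostic
model, statsmodels-style: :class:`DiagnosticModel` is built from a clinical
cohort table and a marker column; :meth:`DiagnosticModel.fit` runs
propensity-score matching, cutoff determination (ROC/Youden and minimal-AIC
dichotomisation), restricted-cubic-spline linearity checks, ordinalisation,
AIC-guided predictor inclusion and nomogram construction, returning a
:class:`DiagnosticResults` carrying the fitted logistic model, its
uncertainties and a ``summary()`` table.  Cohort-level descriptive analyses
(group comparisons, treatment response, confounder screen) are module
functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarker import (
    RcsFit,
    RocResult,
    aic_cutoff_scan,
    nonlinearity_test,
    ordinalize,
    roc_curve,
    youden_cutoff,
)
from .containers import CONTROL_CLASSES
from .logistic import LogisticFit, fit_logistic
from .matching import DEFAULT_COVARIATES, MatchResult, propensity_match
from .stats import benjamini_hochberg, rank_sum_test, signed_rank_test, spearman


# ---------------------------------------------------------------------------
# descriptive cohort analyses


def group_tests(cohort: pd.DataFrame, value_col: str = "igm_g_per_l", contrasts=None) -> pd.DataFrame:
    """Rank-sum comparisons of a marker between diagnosis groups.

    Default contrasts: EMZL against each control class and against the
    pooled controls; p-values BH-adjusted across the contrasts.
    """
    groups = {
        cls: cohort.loc[cohort["diagnosis_class"] == cls, value_col].to_numpy(float)
        for cls in cohort["diagnosis_class"].unique()
    }
    groups["controls"] = cohort.loc[
        cohort["diagnosis_class"].isin(CONTROL_CLASSES), value_col
    ].to_numpy(float)
    if contrasts is None:
        contrasts = [("EMZL", c) for c in list(CONTROL_CLASSES) + ["controls"] if len(groups.get(c, [])) > 0]
    rows = []
    for a, b in contrasts:
        res = rank_sum_test(groups[a], groups[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "median_a": res.median_a,
                "median_b": res.median_b,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def delta_igm_analysis(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment response: change in serum IgM (post minus pre).

    Returns (per_group, between): per-group Wilcoxon signed-rank of the
    change against 0 (subjects with a post-treatment value), and rank-sum
    comparisons of the change between groups that have it.
    """
    has_post = cohort["igm_post_treatment"].notna()
    d = cohort.loc[has_post].copy()
    d["delta_igm"] = d["igm_post_treatment"] - d["igm_g_per_l"]
    per_rows = []
    deltas = {}
    for cls, sub in d.groupby("diagnosis_class", observed=True):
        delta = sub["delta_igm"].to_numpy(float)
        stat, p = signed_rank_test(delta)
        deltas[cls] = delta
        per_rows.append(
            {
                "group": cls,
                "n": delta.size,
                "median_delta": float(np.median(delta)),
                "statistic": stat,
                "p_value": p,
            }
        )
    between_rows = []
    names = list(deltas)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = rank_sum_test(deltas[a], deltas[b])
            between_rows.append({"group_a": a, "group_b": b, "statistic": res.statistic, "p_value": res.p_value})
    return pd.DataFrame(per_rows), pd.DataFrame(between_rows)


def confounder_screen(cohort: pd.DataFrame, value_col: str = "igm_g_per_l") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen age and sex as marker confounders, per diagnosis group.

    Returns (age_table, sex_table): per-group Spearman correlation of the
    marker with age, and per-group rank-sum of the marker between sexes.
    The pooled control classes appear as an extra 'controls' row.
    """
    frames = {cls: sub for cls, sub in cohort.groupby("diagnosis_class", observed=True)}
    frames["controls"] = cohort.loc[cohort["diagnosis_class"].isin(CONTROL_CLASSES)]
    age_rows, sex_rows = [], []
    for name, sub in frames.items():
        rho, p, n = spearman(sub[value_col].to_numpy(float), sub["age_years"].to_numpy(float))
        age_rows.append({"group": name, "rho": rho, "p_value": p, "n": n})
        by_sex = {s: g[value_col].to_numpy(float) for s, g in sub.groupby("sex", observed=True)}
        if len(by_sex) == 2:
            a, b = by_sex.values()
            res = rank_sum_test(a, b)
            sex_rows.append({"group": name, "statistic": res.statistic, "p_value": res.p_value})
        else:
            sex_rows.append({"group": name, "statistic": np.nan, "p_value": np.nan})
    return pd.DataFrame(age_rows), pd.DataFrame(sex_rows)


def age_cutoff(cohort: pd.DataFrame, seed: int = 0) -> tuple[float, float]:
    """ROC-optimal (Youden) age cutoff for EMZL, with younger age as the risk direction.

    Returns (cutoff_years, auc_of_negated_age); the derived model covariate
    is the indicator ``age < cutoff``.
    """
    y = (cohort["diagnosis_class"].astype(str) == "EMZL").astype(int).to_numpy()
    age = cohort["age_years"].to_numpy(float)
    roc = roc_curve(-age, y, n_boot=0, seed=seed)
    cut, _sens, _spec = youden_cutoff(roc)
    return float(-cut), roc.auc


# ---------------------------------------------------------------------------
# model selection and nomogram


def select_model(base_design: pd.DataFrame, candidates: pd.DataFrame, outcome) -> tuple[LogisticFit, pd.DataFrame]:
    """Forward AIC inclusion of candidate predictors over a base model.

    Each candidate column (in listed order) is added to the current design
    iff it lowers the AIC.  Returns the final fit and an inclusion report
    (AIC without/with, decision) — deterministic for a fixed column order.
    """
    design = base_design.copy()
    current = fit_logistic(design, outcome)
    rows = []
    for name in candidates.columns:
        trial = design.copy()
        trial[name] = candidates[name].to_numpy(float)
        fit_try = fit_logistic(trial, outcome)
        include = fit_try.aic < current.aic
        rows.append(
            {
                "candidate": name,
                "aic_without": current.aic,
                "aic_with": fit_try.aic,
                "included": include,
            }
        )
        if include:
            design, current = trial, fit_try
    return current, pd.DataFrame(rows)


@dataclass
class Nomogram:
    """Points re-expression of a logistic fit.

    ``points[predictor][level]`` maps each predictor level to 0-100 points
    (the largest single-predictor coefficient range spans 100).  The total
    points of a covariate pattern determine the predicted probability through
    the inverse logit of ``offset + total_points * scale``.
    """

    points: dict[str, dict[str, float]]
    scale: float       # linear-predictor units per point
    offset: float      # intercept plus the per-predictor minimum contributions
    fit: LogisticFit

    def total_points(self, pattern: dict[str, str]) -> float:
        return float(sum(self.points[pred][lvl] for pred, lvl in pattern.items()))

    def probability(self, total_points: float) -> float:
        eta = self.offset + total_points * self.scale
        return float(1.0 / (1.0 + np.exp(-eta)))

    def predict(self, pattern: dict[str, str]) -> float:
        return self.probability(self.total_points(pattern))


def build_nomogram(fit: LogisticFit, predictor_groups: dict[str, dict[str, dict[str, float]]] | None = None) -> Nomogram:
    """Convert a fitted logistic model into a 0-100 points nomogram.

    ``predictor_groups`` maps predictor -> level -> {term: value}; by
    default every non-intercept term becomes its own binary predictor with
    levels ``no``/``yes``.  Points are affine images of the coefficient
    contributions, anchored at 0 for each predictor's minimum-contribution
    level, with the largest single-predictor range mapped to 100 points.
    """
    if predictor_groups is None:
        predictor_groups = {
            t: {"no": {}, "yes": {t: 1.0}} for t in fit.terms if t != "intercept"
        }
    contrib = {
        pred: {lvl: sum(fit.coef(term) * v for term, v in terms.items()) for lvl, terms in levels.items()}
        for pred, levels in predictor_groups.items()
    }
    ranges = {pred: max(c.values()) - min(c.values()) for pred, c in contrib.items()}
    largest = max(ranges.values())
    if largest <= 0:
        raise ValueError("no predictor has a nonzero coefficient range")
    points = {
        pred: {lvl: 100.0 * (c - min(cs.values())) / largest for lvl, c in cs.items()}
        for pred, cs in contrib.items()
    }
    intercept = fit.coef("intercept") if "intercept" in fit.terms else 0.0
    offset = intercept + sum(min(cs.values()) for cs in contrib.values())
    return Nomogram(points=points, scale=largest / 100.0, offset=offset, fit=fit)


# ---------------------------------------------------------------------------
# the diagnostic model


@dataclass
class CutoffPair:
    """The two marker cutoffs: ROC/Youden and minimal-AIC dichotomisation."""

    roc_cutoff: float
    roc_sens: float
    roc_spec: float
    aic_cutoff: float
    aic_value: float

    @property
    def boundaries(self) -> tuple[float, float]:
        """(low, high) ordinalisation bounds; typically (AIC, ROC) cutoffs."""
        lo, hi = sorted((self.aic_cutoff, self.roc_cutoff))
        if lo == hi:  # degenerate: both criteria picked the same threshold
            hi = float(np.nextafter(hi, np.inf))
        return lo, hi


@dataclass
class DiagnosticResults:
    """Fitted diagnostic model and every intermediate estimate."""

    cohort: pd.DataFrame
    match: MatchResult | None
    marker_roc: RocResult
    cutoffs: CutoffPair
    rcs: RcsFit
    age_cut: float
    fit: LogisticFit
    inclusion_report: pd.DataFrame
    nomogram: Nomogram
    marker: str
    predictors: list[str]

    def design_for(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Model design matrix for a (new) cohort under the fitted cutoffs."""
        lo, hi = self.cutoffs.boundaries
        ords = ordinalize(cohort[self.marker].to_numpy(float), lo, hi)
        cols = {
            "intercept": np.ones(len(cohort)),
            "igm_mid": ords["mid"].to_numpy(float),
            "igm_high": ords["high"].to_numpy(float),
            "age_lt_cutoff": (cohort["age_years"].to_numpy(float) < self.age_cut).astype(float),
        }
        for term in self.fit.terms:
            if term not in cols:
                cols[term] = cohort[term].astype(float).to_numpy()
        design = pd.DataFrame(cols, index=cohort.index)
        return design[self.fit.terms]

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        """preEM-style predicted probability of EMZL for each subject."""
        return self.fit.predict(self.design_for(cohort).to_numpy(float))

    def summary(self) -> str:
        coefs = self.fit.summary()
        lines = [
            "Diagnostic model (logistic, ordinal marker + covariates)",
            "=" * 60,
            f"marker: {self.marker} (g/L); n = {len(self.cohort)}",
            f"ROC AUC (continuous marker): {self.marker_roc.auc:.3f} "
            f"(95% CI {self.marker_roc.auc_ci[0]:.3f}-{self.marker_roc.auc_ci[1]:.3f})",
            f"Youden cutoff: {self.cutoffs.roc_cutoff:.2f} g/L "
            f"(sens {self.cutoffs.roc_sens:.3f}, spec {self.cutoffs.roc_spec:.3f})",
            f"minimal-AIC cutoff: {self.cutoffs.aic_cutoff:.2f} g/L (AIC {self.cutoffs.aic_value:.1f})",
            f"marker non-linearity p: {self.rcs.p_nonlinearity:.3f} "
            f"({self.rcs.knots.size} knots)",
            f"age cutoff: {self.age_cut:.1f} years (covariate: age < cutoff)",
            "-" * 60,
            coefs.to_string(float_format=lambda v: f"{v:.4f}"),
            "-" * 60,
            f"AIC {self.fit.aic:.1f}; log-likelihood {self.fit.log_likelihood:.1f}; "
            f"converged {self.fit.converged}",
        ]
        return "\n".join(lines)

    def calibration(self, cohort: pd.DataFrame | None = None, n_bins: int = 10,
                    bootstrap_reps: int = 0, seed: int = 0) -> pd.DataFrame:
        cohort = self.cohort if cohort is None else cohort
        y = (cohort["diagnosis_class"].astype(str) == "EMZL").astype(float).to_numpy()
        design = self.design_for(cohort)
        return calibration_assess(self.fit, design, y, n_bins=n_bins,
                                  bootstrap_reps=bootstrap_reps, seed=seed)


class DiagnosticModel:
    """Preoperative diagnostic model of EMZL from a serum marker and covariates.

    Parameters
    ----------
    cohort : validated clinical cohort table.
    marker : marker column, g/L (default serum IgM).
    candidate_terms : covariates offered to AIC-guided inclusion on top of
        the ordinal marker and the age indicator.
    match_covariates : covariates of the propensity model used to de-bias
        cutoff determination (set ``match=False`` to skip matching).

    ``fit()`` returns a :class:`DiagnosticResults`.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        marker: str = "igm_g_per_l",
        candidate_terms=("lacrimal_involvement", "bilateral"),
        match: bool = True,
        match_covariates=DEFAULT_COVARIATES,
        n_boot: int = 2000,
        knots: int = 4,
        cutoff_strategy: str = "youden",
    ) -> None:
        self.cohort = cohort.reset_index(drop=True)
        self.marker = marker
        self.candidate_terms = list(candidate_terms)
        self.match = match
        self.match_covariates = match_covariates
        self.n_boot = n_boot
        self.knots = knots
        self.cutoff_strategy = cutoff_strategy

    def fit(self, seed: int = 0) -> DiagnosticResults:
        cohort = self.cohort
        y_all = (cohort["diagnosis_class"].astype(str) == "EMZL").astype(int).to_numpy()
        x_all = cohort[self.marker].to_numpy(float)

        match_res = None
        cut_frame = cohort
        if self.match:
            match_res = propensity_match(cohort, self.match_covariates)
            matched = set(match_res.matched_ids)
            cut_frame = cohort[cohort["subject_id"].isin(matched)]
        x_cut = cut_frame[self.marker].to_numpy(float)
        y_cut = (cut_frame["diagnosis_class"].astype(str) == "EMZL").astype(int).to_numpy()

        marker_roc = roc_curve(x_all, y_all, n_boot=self.n_boot, seed=seed)
        roc_matched = roc_curve(x_cut, y_cut, n_boot=0, seed=seed)
        roc_cut, sens, spec = youden_cutoff(roc_matched, strategy=self.cutoff_strategy)
        scan = aic_cutoff_scan(x_cut, y_cut)
        cutoffs = CutoffPair(roc_cutoff=roc_cut, roc_sens=sens, roc_spec=spec,
                             aic_cutoff=scan.cutoff, aic_value=scan.aic)
        rcs = nonlinearity_test(x_cut, y_cut, n_knots=self.knots)
        age_cut, _ = age_cutoff(cohort, seed=seed)

        lo, hi = cutoffs.boundaries
        ords = ordinalize(x_all, lo, hi)
        base = pd.DataFrame(
            {
                "intercept": np.ones(len(cohort)),
                "igm_mid": ords["mid"].to_numpy(float),
                "igm_high": ords["high"].to_numpy(float),
                "age_lt_cutoff": (cohort["age_years"].to_numpy(float) < age_cut).astype(float),
            }
        )
        candidates = pd.DataFrame(
            {t: cohort[t].astype(float).to_numpy() for t in self.candidate_terms}
        )
        fit, report = select_model(base, candidates, y_all.astype(float))
        groups = {
            "igm_level": {
                "low": {},
                "mid": {"igm_mid": 1.0},
                "high": {"igm_high": 1.0},
            },
            "age_lt_cutoff": {"no": {}, "yes": {"age_lt_cutoff": 1.0}},
        }
        for t in fit.terms:
            if t not in ("intercept", "igm_mid", "igm_high", "age_lt_cutoff"):
                groups[t] = {"no": {}, "yes": {t: 1.0}}
        nomogram = build_nomogram(fit, groups)
        return DiagnosticResults(
            cohort=cohort,
            match=match_res,
            marker_roc=marker_roc,
            cutoffs=cutoffs,
            rcs=rcs,
            age_cut=age_cut,
            fit=fit,
            inclusion_report=report,
            nomogram=nomogram,
            marker=self.marker,
            predictors=[t for t in fit.terms if t != "intercept"],
        )


# ---------------------------------------------------------------------------
# split / validation / calibration


@dataclass
class SplitValidation:
    derivation: pd.DataFrame
    validation: pd.DataFrame
    results: DiagnosticResults
    roc_table: pd.DataFrame
    validation_empty: bool = False


def stratified_split(cohort: pd.DataFrame, derivation_fraction: float, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded stratified split by diagnosis class (proportions within +-1)."""
    if not 0.0 < derivation_fraction <= 1.0:
        raise ValueError("derivation_fraction must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 51]))
    deriv_idx = []
    for _, sub in cohort.groupby("diagnosis_class", observed=True):
        idx = sub.index.to_numpy().copy()
        rng.shuffle(idx)
        n_d = int(round(derivation_fraction * idx.size))
        deriv_idx.extend(idx[:n_d])
    deriv_mask = cohort.index.isin(deriv_idx)
    return cohort[deriv_mask], cohort[~deriv_mask]


def split_and_validate(
    cohort: pd.DataFrame,
    derivation_fraction: float = 0.6,
    seed: int = 0,
    **model_kwargs,
) -> SplitValidation:
    """Derivation/validation workflow: fit on a stratified 60%, test on 40%.

    The model (cutoffs, age indicator, predictor selection, nomogram) is
    built on the derivation set only; the ROC table compares the combined
    model score against the continuous and the ordinal marker on both sets.
    """
    deriv, valid = stratified_split(cohort, derivation_fraction, seed)
    model = DiagnosticModel(deriv, **model_kwargs)
    results = model.fit(seed=seed)
    rows = []
    for name, frame in (("derivation", deriv), ("validation", valid)):
        if len(frame) == 0:
            continue
        y = (frame["diagnosis_class"].astype(str) == "EMZL").astype(int).to_numpy()
        if y.min() == y.max():
            continue
        score = results.predict(frame)
        cont = frame[results.marker].to_numpy(float)
        lo, hi = results.cutoffs.boundaries
        ords = ordinalize(cont, lo, hi)["level"].to_numpy(float)
        for score_name, vals in (("model", score), ("continuous_marker", cont), ("ordinal_marker", ords)):
            rows.append({"set": name, "score": score_name, "auc": roc_curve(vals, y, n_boot=0).auc})
    return SplitValidation(
        derivation=deriv,
        validation=valid,
        results=results,
        roc_table=pd.DataFrame(rows),
        validation_empty=len(valid) == 0,
    )


def calibration_assess(
    fit: LogisticFit,
    design: pd.DataFrame,
    outcome,
    n_bins: int = 10,
    bootstrap_reps: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibration table: observed vs mean predicted frequency per risk bin.

    Subjects are ranked by predicted probability and cut into ``n_bins``
    equal-count bins.  With ``bootstrap_reps`` > 0 an optimism-corrected
    observed frequency is added: models refit on bootstrap resamples are
    evaluated on the original data and the mean apparent-minus-test gap per
    bin is subtracted from the apparent curve.
    """
    X = design.to_numpy(float)
    y = np.asarray(outcome, float)
    p = fit.predict(X)
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for i, b in enumerate(bins):
        rows.append(
            {
                "bin": i,
                "n": b.size,
                "mean_predicted": float(p[b].mean()),
                "observed": float(y[b].mean()),
            }
        )
    table = pd.DataFrame(rows)
    if bootstrap_reps:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
        opt = np.zeros(n_bins)
        done = 0
        for _ in range(bootstrap_reps):
            idx = rng.integers(0, len(y), size=len(y))
            if y[idx].min() == y[idx].max():
                continue
            try:
                bfit = fit_logistic(X[idx], y[idx], terms=fit.terms)
            except ValueError:  # resample lost a predictor level entirely
                continue
            p_boot_on_boot = bfit.predict(X[idx])
            p_boot_on_orig = bfit.predict(X)
            app = _bin_gap(p_boot_on_boot, y[idx], n_bins)
            test = _bin_gap(p_boot_on_orig, y, n_bins)
            opt += app - test
            done += 1
        if done:
            table["optimism"] = opt / done
            table["observed_corrected"] = table["observed"] - table["optimism"]
    return table


def _bin_gap(p, y, n_bins):
    order = np.argsort(p, kind="stable")
    gaps = np.empty(n_bins)
    for i, b in enumerate(np.array_split(order, n_bins)):
        gaps[i] = y[b].mean() - p[b].mean()
    return gaps
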