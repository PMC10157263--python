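"""Continuous serum-biomarker evaluation.

Covers the threshold-finding toolkit for a continuous marker (serum IgM in
g/L) against a binary diagnosis:

* empirical ROC curve with tie-corrected AUC and a stratified-bootstrap
  confidence interval;
* Youden-index (or closest-to-(0,1)) optimal cutoff;
* restricted cubic spline (natural cubic) basis and a likelihood-ratio test
  of non-linearity of the marker's effect on the log-odds;
* a minimal-AIC dichotomisation scan returning the cutoff whose indicator
  best explains the outcome;
* ordinalisation of the marker into low/mid/high using the two cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .logistic import LogisticFit, fit_logistic


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    """Empirical ROC curve: for each threshold t, a subject is called
    positive when value >= t.  Thresholds ascend over the unique observed
    values plus a +inf sentinel, so sensitivity is non-increasing and
    specificity non-decreasing along the grid."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int

    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def _auc_rank(values: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected AUC: Mann-Whitney U / (n_pos * n_neg), ties counted 1/2."""
    ranks = stats.rankdata(values)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(values, labels, n_boot: int = 2000, seed: int = 0, ci_level: float = 0.95) -> RocResult:
    """Empirical ROC with tie-corrected AUC and stratified-bootstrap CI.

    ``labels`` are 0/1 with 1 = diseased; higher values flag disease.
    The CI is percentile-method over ``n_boot`` resamples drawn within each
    class (set ``n_boot=0`` to skip).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    if values.size != labels.size:
        raise ValueError("values and labels lengths differ")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    thresholds = np.concatenate([np.unique(values), [np.inf]])
    pos_vals = values[labels == 1]
    neg_vals = values[labels == 0]
    sens = np.array([(pos_vals >= t).mean() for t in thresholds])
    spec = np.array([(neg_vals < t).mean() for t in thresholds])
    auc = _auc_rank(values, labels)
    ci = (float("nan"), float("nan"))
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos_vals, size=n_pos, replace=True)
            bn = rng.choice(neg_vals, size=n_neg, replace=True)
            boots[b] = _auc_rank(
                np.concatenate([bp, bn]),
                np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)]),
            )
        alpha = 1.0 - ci_level
        ci = (float(np.quantile(boots, alpha / 2)), float(np.quantile(boots, 1 - alpha / 2)))
    return RocResult(thresholds, sens, spec, auc, ci, n_pos, n_neg)


def youden_cutoff(roc: RocResult, strategy: str = "youden") -> tuple[float, float, float]:
    """Optimal ROC cutoff as (cutoff, sensitivity, specificity).

    ``strategy='youden'`` maximises J = sensitivity + specificity - 1;
    ``strategy='closest'`` minimises the Euclidean distance to the ideal
    (sens, spec) = (1, 1) corner.  Ties are broken toward the higher
    specificity, then the lower cutoff value.
    """
    if strategy == "youden":
        crit = roc.youden()
        best = np.max(crit)
        idx = np.flatnonzero(np.isclose(crit, best))
    elif strategy == "closest":
        d = np.hypot(1.0 - roc.sensitivity, 1.0 - roc.specificity)
        best = np.min(d)
        idx = np.flatnonzero(np.isclose(d, best))
    else:
        raise ValueError("strategy must be 'youden' or 'closest'")
    spec = roc.specificity[idx]
    idx = idx[np.isclose(spec, spec.max())]
    i = idx[np.argmin(roc.thresholds[idx])]
    return float(roc.thresholds[i]), float(roc.sensitivity[i]), float(roc.specificity[i])


# ---------------------------------------------------------------------------
# restricted cubic splines


def default_knots(x, n_knots: int = 4) -> np.ndarray:
    """Quantile-based knot placement (3-5 knots, standard percentiles)."""
    qs = {
        3: (10, 50, 90),
        4: (5, 35, 65, 95),
        5: (5, 27.5, 50, 72.5, 95),
    }
    if n_knots not in qs:
        raise ValueError("n_knots must be 3, 4 or 5")
    knots = np.percentile(np.asarray(x, float), qs[n_knots])
    if np.unique(knots).size != n_knots:
        raise ValueError("degenerate data: knots are not distinct")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis: k knots -> k-1 columns incl. the linear term.

    The fitted function is a natural cubic spline — value and first two
    derivatives continuous, linear beyond the boundary knots.  Nonlinear
    columns are scaled by the squared boundary-knot span so coefficients
    stay on a comparable scale.
    """
    x = np.asarray(x, float)
    t = np.asarray(knots, float)
    if t.size < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")
    k = t.size
    norm = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclass
class RcsFit:
    """RCS logistic fit with the linearity likelihood-ratio test."""

    knots: np.ndarray
    coefficients: np.ndarray
    log_likelihood: float
    lr_statistic: float
    df: int
    p_nonlinearity: float
    fit: LogisticFit
    linear_fit: LogisticFit

    @property
    def aic(self) -> float:
        return self.fit.aic

    def predict_logit(self, x) -> np.ndarray:
        X = np.column_stack([np.ones(np.size(x)), rcs_basis(x, self.knots)])
        return X @ self.coefficients


def nonlinearity_test(x, y_binary, knots=None, n_knots: int = 4) -> RcsFit:
    """Test linearity of a marker's effect on the log-odds of disease.

    Fits logistic models with the full RCS basis and with the linear term
    only; ``p_nonlinearity`` is the likelihood-ratio chi-square test on the
    k-2 nonlinear coefficients.  A large p is consistent with a linear fit.
    """
    x = np.asarray(x, float)
    y = np.asarray(y_binary, float)
    if knots is None:
        knots = default_knots(x, n_knots)
    knots = np.asarray(knots, float)
    B = rcs_basis(x, knots)
    Xfull = np.column_stack([np.ones(x.size), B])
    Xlin = Xfull[:, :2]
    full = fit_logistic(Xfull, y, terms=["intercept", "linear"] + [f"rcs{j}" for j in range(1, knots.size - 1)])
    lin = fit_logistic(Xlin, y, terms=["intercept", "linear"])
    lr = 2.0 * (full.log_likelihood - lin.log_likelihood)
    lr = max(lr, 0.0)
    df = knots.size - 2
    p = float(stats.chi2.sf(lr, df)) if lr > 0 else 1.0
    return RcsFit(
        knots=knots,
        coefficients=full.params,
        log_likelihood=full.log_likelihood,
        lr_statistic=lr,
        df=df,
        p_nonlinearity=p,
        fit=full,
        linear_fit=lin,
    )


def rcs_knot_scan(x, y_binary, candidates=(3, 4, 5)) -> RcsFit:
    """Secondary routine: pick the RCS knot count minimising AIC."""
    fits = [nonlinearity_test(x, y_binary, n_knots=k) for k in candidates]
    return min(fits, key=lambda f: f.aic)


# ---------------------------------------------------------------------------
# AIC dichotomisation scan


@dataclass
class AicScanResult:
    cutoff: float
    aic: float
    table: pd.DataFrame  # columns: cutoff, aic, separation


def aic_cutoff_scan(x, y_binary, grid=None) -> AicScanResult:
    """Scan candidate dichotomisation cutoffs, minimising the logistic AIC.

    For each candidate c the model ``logit P(y=1) = b0 + b1*1[x >= c]`` is
    fitted; the returned cutoff minimises AIC (ties toward the smaller c).
    The default grid is the unique observed values between the 5th and 95th
    percentiles.  Grids that split the outcome perfectly are handled by the
    fitter's ridge fallback and flagged in the scan table.
    """
    x = np.asarray(x, float)
    y = np.asarray(y_binary, float)
    if grid is None:
        lo, hi = np.percentile(x, [5, 95])
        grid = np.unique(x[(x >= lo) & (x <= hi)])
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty cutoff grid")
    rows = []
    for c in np.sort(grid):
        ind = (x >= c).astype(float)
        if ind.min() == ind.max():  # degenerate indicator: intercept-only model
            fit = fit_logistic(np.ones((x.size, 1)), y, terms=["intercept"])
            aic = fit.aic + 2.0  # charge for the unused slope to keep k comparable
            sep = False
        else:
            fit = fit_logistic(np.column_stack([np.ones(x.size), ind]), y, terms=["intercept", "indicator"])
            aic = fit.aic
            sep = fit.separation
        rows.append({"cutoff": float(c), "aic": float(aic), "separation": sep})
    table = pd.DataFrame(rows)
    best = table.loc[table["aic"].idxmin()]  # idxmin takes the first (smallest c) on ties
    return AicScanResult(cutoff=float(best["cutoff"]), aic=float(best["aic"]), table=table)


# ---------------------------------------------------------------------------
# ordinalisation


def ordinalize(values, low_cut: float, high_cut: float) -> pd.DataFrame:
    """Code a continuous marker into ordered low/mid/high levels.

    low: value < low_cut; mid: low_cut <= value < high_cut; high:
    value >= high_cut (boundary values go to the upper level).  Returns a
    frame with the integer code (0/1/2), the label, and the two dummy
    indicators used in modelling.
    """
    if not low_cut < high_cut:
        raise ValueError("low_cut must be < high_cut")
    v = np.asarray(values, float)
    code = np.where(v >= high_cut, 2, np.where(v >= low_cut, 1, 0))
    labels = np.array(["low", "mid", "high"])[code]
    return pd.DataFrame(
        {
            "value": v,
            "level": code,
            "label": labels,
            "mid": (code == 1).astype(int),
            "high": (code == 2).astype(int),
        }
    )
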