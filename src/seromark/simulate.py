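"""Synthetic paired-omics, clonality and case-control cohort generators.

The generators reproduce the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without patient data:

* :func:`generate_paired_omics` — a serum-proteome and a tissue-transcriptome
  layer over ~1000 mapped protein-mRNA pairs, with a small set of planted
  tumour-derived markers that are up-regulated in cases in both layers and
  rank-correlated across layers through a shared per-subject latent factor.
* :func:`generate_cohort` — a four-class case-control clinical table
  (EMZL vs other lymphoma subtypes, lymphoid hyperplasia, chronic orbital
  inflammation) with log-normal serum IgM, an IgM shift in EMZL, a negative
  age trend of IgM confined to the control classes, and an expected
  post-treatment IgM decrease in cases.
* :func:`generate_clonality` — per-subject kappa/lambda light-chain
  abundances with configurable light-chain restriction in cases.

Every generator is a pure function of its config (including the seed);
identical configs give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, PairedOmics, PROTEOME, TRANSCRIPTOME

_STREAM = {"omics": 11, "cohort": 23, "clonality": 37, "split": 51}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Derive the documented per-stage RNG sub-stream from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM[stream]]))


# ---------------------------------------------------------------------------
# configs


@dataclass
class OmicsSimConfig:
    """Study conditions for the paired-omics generator.

    Defaults mirror the profiled cohorts: a serum-proteome arm of 28 cases +
    30 controls, a tissue-transcriptome arm of 38 cases + 31 controls, 1003
    mapped protein-mRNA pairs, and one planted tumour-derived marker with
    proteomic log2 fold change 2.64, transcriptomic 2.0 and cross-layer
    Spearman correlation 0.6.
    """

    n_cases: int = 28
    n_controls: int = 30
    n_cases_trans: int | None = 38
    n_controls_trans: int | None = 31
    n_pairs: int = 1003
    n_planted: int = 1
    planted_log2fc_prot: float = 2.64
    planted_log2fc_trans: float = 2.0
    cross_omics_rho: float = 0.6
    shared_subject_fraction: float = 0.75
    noise_sd: float = 0.8
    planted_symbols: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_planted <= self.n_pairs:
            raise ValueError("n_planted must lie in [0, n_pairs]")
        if not 0.0 <= self.cross_omics_rho <= 1.0:
            raise ValueError("cross_omics_rho must lie in [0, 1]")
        if not 0.0 < self.shared_subject_fraction <= 1.0:
            raise ValueError("shared_subject_fraction must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.planted_symbols is not None and len(self.planted_symbols) != self.n_planted:
            raise ValueError("planted_symbols length must equal n_planted")


@dataclass
class CohortSimConfig:
    """Study conditions for the clinical case-control cohort generator.

    ``n_per_class`` is (EMZL, other lymphoma, lymphoid hyperplasia, chronic
    inflammation); the default (68, 33, 26, 78) reproduces the 205-patient
    case-control cohort.  Serum IgM is log-normal per class; within the
    control classes log IgM declines with age at ``age_igm_slope_controls``
    per year, while in EMZL it is age-independent.
    """

    n_per_class: tuple[int, int, int, int] = (68, 33, 26, 78)
    igm_log_mean_case: float = float(np.log(1.7))
    igm_log_mean_control: float = float(np.log(0.85))
    igm_log_sd: float = 0.5
    age_igm_slope_controls: float = -0.012
    lacrimal_prob_case: float = 0.5
    lacrimal_prob_control: float = 0.2
    treatment_effect: float = -0.5
    treatment_noise_sd: float = 0.25
    age_mean: float = 58.0
    age_sd: float = 16.0
    age_shift_case: float = -8.0
    age_range: tuple[float, float] = (18.0, 90.0)
    bilateral_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_class = tuple(int(n) for n in self.n_per_class)
        if len(self.n_per_class) != 4 or any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be four non-negative counts")
        if sum(self.n_per_class) == 0:
            raise ValueError("at least one class count must be positive")
        for name in ("lacrimal_prob_case", "lacrimal_prob_control", "bilateral_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.igm_log_sd <= 0:
            raise ValueError("igm_log_sd must be > 0")


@dataclass
class ClonalitySimConfig:
    """Study conditions for the light-chain restriction generator.

    ``restriction`` is the expected share of total light-chain output from
    the dominant chain in cases (0.5 = balanced/polyclonal, 1 = fully
    restricted); the dominant chain (kappa or lambda) is random per subject.
    Controls are polyclonal (expected share 0.5).  Shares are Beta with the
    stated mean and concentration ``1/noise_sd**2``; totals are log-normal
    around ``total_ig_scale``.
    """

    n_cases: int = 30
    n_controls: int = 30
    restriction: float = 0.9
    total_ig_scale: float = 100.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if not 0.5 <= self.restriction <= 1.0:
            raise ValueError("restriction must lie in [0.5, 1]")
        if self.total_ig_scale <= 0 or self.noise_sd <= 0:
            raise ValueError("total_ig_scale and noise_sd must be > 0")


_CONFIG_TYPES = {
    "omics": OmicsSimConfig,
    "cohort": CohortSimConfig,
    "clonality": ClonalitySimConfig,
}


def config_to_yaml(config, path=None) -> str:
    """Serialise a sim config to YAML (round-trippable via load_config)."""
    kind = next(k for k, t in _CONFIG_TYPES.items() if isinstance(config, t))
    payload = {"kind": kind, **_plain(dataclasses.asdict(config))}
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def config_from_yaml(source):
    """Load a sim config from a YAML string or path; unknown keys rejected."""
    try:
        text = open(source, encoding="utf-8").read()
    except (OSError, TypeError):
        text = source
    payload = yaml.safe_load(text)
    kind = payload.pop("kind", None)
    if kind not in _CONFIG_TYPES:
        raise ValueError(f"unknown or missing config kind {kind!r}")
    cls = _CONFIG_TYPES[kind]
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in payload and isinstance(payload[f.name], list) and "tuple" in str(f.type):
            payload[f.name] = tuple(payload[f.name])
    return cls(**payload)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# paired omics


@dataclass
class PairedOmicsSim:
    """Output bundle of :func:`generate_paired_omics`."""

    paired: PairedOmics
    planted_genes: list[str]
    prot_case_ids: list[str]
    prot_control_ids: list[str]
    trans_case_ids: list[str]
    trans_control_ids: list[str]

    def truth(self) -> dict:
        """JSON-serialisable planted-truth sidecar."""
        return {
            "planted_genes": list(self.planted_genes),
            "prot_case_ids": list(self.prot_case_ids),
            "prot_control_ids": list(self.prot_control_ids),
            "trans_case_ids": list(self.trans_case_ids),
            "trans_control_ids": list(self.trans_control_ids),
            "shared_subjects": list(self.paired.shared_subjects),
        }


def generate_paired_omics(config: OmicsSimConfig) -> PairedOmicsSim:
    """Simulate a serum-proteome + tissue-transcriptome pair with planted markers.

    Abundances are log2-normal around feature-specific baselines; planted
    markers add the configured per-layer log2 fold change in cases, and their
    residuals share a per-subject latent factor over the subjects profiled in
    both layers, inducing the target cross-layer Spearman correlation.
    Non-planted features have zero expected fold change and zero expected
    cross-layer correlation.
    """
    rng = _rng(config.seed, "omics")
    ncp, nkp = config.n_cases, config.n_controls
    nct = config.n_cases_trans if config.n_cases_trans is not None else ncp
    nkt = config.n_controls_trans if config.n_controls_trans is not None else nkp

    # shared subjects: a fraction of the smaller arm, per class stratum
    sh_cases = round(config.shared_subject_fraction * min(ncp, nct))
    sh_ctrl = round(config.shared_subject_fraction * min(nkp, nkt))

    def subject_ids(prefix, n_shared, n_prot_only, n_trans_only):
        shared = [f"{prefix}{i:03d}" for i in range(n_shared)]
        prot = shared + [f"{prefix}P{i:03d}" for i in range(n_prot_only)]
        trans = shared + [f"{prefix}T{i:03d}" for i in range(n_trans_only)]
        return shared, prot, trans

    shc, prot_cases, trans_cases = subject_ids("CASE", sh_cases, ncp - sh_cases, nct - sh_cases)
    shk, prot_ctrls, trans_ctrls = subject_ids("CTRL", sh_ctrl, nkp - sh_ctrl, nkt - sh_ctrl)
    prot_subjects = prot_cases + prot_ctrls
    trans_subjects = trans_cases + trans_ctrls
    shared_subjects = shc + shk

    n = config.n_pairs
    planted = np.zeros(n, dtype=bool)
    planted[: config.n_planted] = True
    genes = [f"GENE{i + 1:04d}" for i in range(n)]
    if config.planted_symbols is not None:
        for i, sym in enumerate(config.planted_symbols):
            genes[i] = sym
    pair_map = [(f"PROT_{g}", f"TRNS_{g}", g) for g in genes]

    base_prot = rng.normal(5.0, 2.0, size=n)
    base_trans = rng.normal(5.0, 2.0, size=n)

    # Pearson loading giving the target Spearman rho under bivariate normality
    r = 2.0 * np.sin(np.pi * config.cross_omics_rho / 6.0)

    def build_layer(base, fc, subjects, cases, layer):
        is_case = np.array([s in set(cases) for s in subjects])
        log2 = base[:, None] + np.where(is_case[None, :], fc[:, None], 0.0)
        return log2, is_case

    fc_prot = np.where(planted, config.planted_log2fc_prot, 0.0)
    fc_trans = np.where(planted, config.planted_log2fc_trans, 0.0)
    log2_prot, _ = build_layer(base_prot, fc_prot, prot_subjects, prot_cases, PROTEOME)
    log2_trans, _ = build_layer(base_trans, fc_trans, trans_subjects, trans_cases, TRANSCRIPTOME)

    eps_prot = rng.normal(0.0, 1.0, size=(n, len(prot_subjects)))
    eps_trans = rng.normal(0.0, 1.0, size=(n, len(trans_subjects)))
    if shared_subjects and config.n_planted:
        z = rng.normal(0.0, 1.0, size=(config.n_planted, len(shared_subjects)))
        pcols = [prot_subjects.index(s) for s in shared_subjects]
        tcols = [trans_subjects.index(s) for s in shared_subjects]
        a, b = np.sqrt(r), np.sqrt(1.0 - r)
        eps_prot[np.ix_(np.flatnonzero(planted), pcols)] = a * z + b * eps_prot[np.ix_(np.flatnonzero(planted), pcols)]
        eps_trans[np.ix_(np.flatnonzero(planted), tcols)] = a * z + b * eps_trans[np.ix_(np.flatnonzero(planted), tcols)]
    log2_prot = log2_prot + config.noise_sd * eps_prot
    log2_trans = log2_trans + config.noise_sd * eps_trans

    proteome = ExpressionMatrix(PROTEOME, [p for p, _, _ in pair_map], prot_subjects, 2.0**log2_prot)
    transcriptome = ExpressionMatrix(TRANSCRIPTOME, [t for _, t, _ in pair_map], trans_subjects, 2.0**log2_trans)
    paired = PairedOmics(proteome, transcriptome, pair_map, shared_subjects)
    return PairedOmicsSim(
        paired=paired,
        planted_genes=[genes[i] for i in np.flatnonzero(planted)],
        prot_case_ids=prot_cases,
        prot_control_ids=prot_ctrls,
        trans_case_ids=trans_cases,
        trans_control_ids=trans_ctrls,
    )


# ---------------------------------------------------------------------------
# clinical cohort

_CLASS_NAMES = ("EMZL", "other_lymphoma", "lymphoid_hyperplasia", "chronic_inflammation")
_SITES = ("orbit", "conjunctiva", "lacrimal_gland", "eyelid")
_SITE_PROBS = (0.45, 0.3, 0.15, 0.1)
_EPOCH = pd.Timestamp("2012-01-01")
_DIAGNOSIS_WINDOW_DAYS = 3653  # ten calendar years


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate the four-class clinical cohort table.

    Serum IgM is log-normal per class.  In the three control classes the
    conditional mean of log IgM declines with age (centred at the age mean)
    at ``age_igm_slope_controls`` per year; in EMZL IgM is independent of
    age.  EMZL rows carry a post-treatment IgM with expected change
    ``treatment_effect`` (g/L, additive).
    """
    rng = _rng(config.seed, "cohort")
    lo, hi = config.age_range
    rows = []
    counter = 0
    for cls, n in zip(_CLASS_NAMES, config.n_per_class):
        if n == 0:
            continue
        is_case = cls == "EMZL"
        age_mu = config.age_mean + (config.age_shift_case if is_case else 0.0)
        age = _truncated_normal(rng, age_mu, config.age_sd, lo, hi, n)
        mu = config.igm_log_mean_case if is_case else config.igm_log_mean_control
        log_igm = mu + rng.normal(0.0, config.igm_log_sd, size=n)
        if not is_case:
            log_igm = log_igm + config.age_igm_slope_controls * (age - config.age_mean)
        igm = np.exp(log_igm)
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        date = _EPOCH + pd.to_timedelta(rng.integers(0, _DIAGNOSIS_WINDOW_DAYS, size=n), unit="D")
        bilateral = rng.random(n) < config.bilateral_prob
        site = rng.choice(_SITES, p=_SITE_PROBS, size=n)
        p_lac = config.lacrimal_prob_case if is_case else config.lacrimal_prob_control
        lacrimal = rng.random(n) < p_lac
        if is_case:
            post = igm + config.treatment_effect + rng.normal(0.0, config.treatment_noise_sd, size=n)
            post = np.maximum(post, 0.01)
        else:
            post = np.full(n, np.nan)
        for i in range(n):
            counter += 1
            rows.append(
                {
                    "subject_id": f"S{counter:04d}",
                    "diagnosis_class": cls,
                    "igm_g_per_l": igm[i],
                    "age_years": age[i],
                    "sex": sex[i],
                    "date_of_diagnosis": date[i],
                    "bilateral": bool(bilateral[i]),
                    "disease_site": site[i],
                    "lacrimal_involvement": bool(lacrimal[i]),
                    "igm_post_treatment": post[i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clonality


def generate_clonality(config: ClonalitySimConfig) -> pd.DataFrame:
    """Simulate per-subject kappa/lambda light-chain abundances.

    Returns a frame with columns ``subject_id, kappa, lambda_, group`` where
    group is ``case`` or ``control``.  For cases the dominant-chain share of
    total output has expectation ``restriction`` with a random dominant
    chain per subject; controls are balanced in expectation.
    """
    rng = _rng(config.seed, "clonality")
    n = config.n_cases + config.n_controls
    is_case = np.arange(n) < config.n_cases
    conc = 1.0 / config.noise_sd**2
    share = np.empty(n)
    mean_case = config.restriction
    if mean_case >= 1.0:
        share[is_case] = 1.0
    else:
        share[is_case] = rng.beta(mean_case * conc, (1.0 - mean_case) * conc, size=int(is_case.sum()))
    share[~is_case] = rng.beta(0.5 * conc, 0.5 * conc, size=int((~is_case).sum()))
    total = config.total_ig_scale * np.exp(rng.normal(0.0, config.noise_sd, size=n))
    kappa_dominant = rng.random(n) < 0.5
    dom = share * total
    rec = (1.0 - share) * total
    kappa = np.where(kappa_dominant, dom, rec)
    lam = np.where(kappa_dominant, rec, dom)
    return pd.DataFrame(
        {
            "subject_id": [f"C{i + 1:04d}" for i in range(n)],
            "kappa": kappa,
            "lambda_": lam,
            "group": np.where(is_case, "case", "control"),
        }
    )


def generate_clonality_paired(config: ClonalitySimConfig, marker_loading: float = 1.0):
    """Simulate transcriptome and proteome clonality layers plus a serum marker.

    In cases the dominant chain and its share are a single subject-level
    clonal factor shared by both layers (with independent log-normal
    measurement noise on each chain), and the serum marker abundance is
    driven by the same factor; in controls the two layers and the marker are
    independent.  Used to probe cross-layer and score-vs-marker correlation.
    """
    rng = _rng(config.seed, "clonality")
    n = config.n_cases + config.n_controls
    is_case = np.arange(n) < config.n_cases
    conc = 1.0 / config.noise_sd**2
    subject_ids = [f"C{i + 1:04d}" for i in range(n)]

    def draw_share(mean, size):
        if mean >= 1.0:
            return np.ones(size)
        return rng.beta(mean * conc, (1.0 - mean) * conc, size=size)

    share_case = draw_share(config.restriction, int(is_case.sum()))
    kappa_dom = rng.random(n) < 0.5
    layers = {}
    meas_sd = config.noise_sd / 2.0  # measurement noise, smaller than biological spread
    for layer in ("transcriptome", "proteome"):
        share = np.empty(n)
        share[is_case] = share_case
        share[~is_case] = rng.beta(0.5 * conc, 0.5 * conc, size=int((~is_case).sum()))
        total = config.total_ig_scale * np.exp(rng.normal(0.0, config.noise_sd, size=n))
        dom = share * total * np.exp(rng.normal(0.0, meas_sd, size=n))
        rec = (1.0 - share) * total * np.exp(rng.normal(0.0, meas_sd, size=n))
        layers[layer] = pd.DataFrame(
            {
                "subject_id": subject_ids,
                "kappa": np.where(kappa_dom, dom, rec),
                "lambda_": np.where(kappa_dom, rec, dom),
                "group": np.where(is_case, "case", "control"),
            }
        )
    s = np.full(n, 0.5)
    s[is_case] = np.clip(share_case, 1e-6, 1.0 - 1e-6)
    clonal_factor = np.zeros(n)
    clonal_factor[is_case] = np.abs(np.log2(s[is_case] / (1.0 - s[is_case])))
    marker = np.exp(
        marker_loading * clonal_factor + rng.normal(0.0, config.noise_sd, size=n)
    )
    marker = pd.DataFrame({"subject_id": subject_ids, "marker": marker, "group": np.where(is_case, "case", "control")})
    return layers["transcriptome"], layers["proteome"], marker
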