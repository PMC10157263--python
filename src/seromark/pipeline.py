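"""End-to-end reproducible pipeline: simulate -> discovery -> model -> report.

Each stage logs its seed, parameters and input hashes; all tabular outputs
are TSV, models and reports JSON, figures SVG.  Given the same config the
result bundle is byte-identical (timestamps are confined to the log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonality as clon
from . import crossomics as co
from . import io as sio
from .diagnostic import (
    confounder_screen,
    delta_igm_analysis,
    group_tests,
    split_and_validate,
)
from .simulate import (
    ClonalitySimConfig,
    CohortSimConfig,
    OmicsSimConfig,
    generate_clonality_paired,
    generate_cohort,
    generate_paired_omics,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.10g")
    log.info("wrote %s (sha256 %s)", path, _hash(path))


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n", encoding="utf-8")
    log.info("wrote %s (sha256 %s)", path, _hash(path))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def run_pipeline(config: sio.PipelineConfig) -> dict:
    """Run every stage under the config; returns the in-memory result bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline seed=%d outdir=%s", config.seed, outdir)
    bundle: dict = {}
    stage = "simulate"
    try:
        if config.simulate:
            omics_cfg = OmicsSimConfig(**{"seed": config.seed, **config.omics})
            cohort_cfg = CohortSimConfig(**{"seed": config.seed, **config.cohort_sim})
            clon_cfg = ClonalitySimConfig(**{"seed": config.seed, **config.clonality_sim})
            log.info("simulate: %s | %s | %s", omics_cfg, cohort_cfg, clon_cfg)
            sim = generate_paired_omics(omics_cfg)
            paired = sim.paired
            cohort = generate_cohort(cohort_cfg)
            trans_cl, prot_cl, marker = generate_clonality_paired(clon_cfg)
            sio.write_expression_matrix(paired.proteome, outdir / "proteome.tsv")
            sio.write_expression_matrix(paired.transcriptome, outdir / "transcriptome.tsv")
            sio.write_pair_map(paired.pair_map, outdir / "pair_map.tsv")
            sio.write_cohort(cohort, outdir / "cohort.tsv")
            sio.write_truth_sidecar(sim.truth(), outdir / "planted_truth.json")
            de_groups = dict(
                prot=(sim.prot_case_ids, sim.prot_control_ids),
                trans=(sim.trans_case_ids, sim.trans_control_ids),
            )
            bundle["sim"] = sim
        else:
            paired = sio.load_paired_omics(config)
            cohort = sio.read_cohort(config.cohort_path)
            trans_cl = prot_cl = marker = None
            case_pref = [s for s in paired.proteome.subject_ids if s.startswith("CASE")]
            ctrl_pref = [s for s in paired.proteome.subject_ids if not s.startswith("CASE")]
            de_groups = dict(
                prot=(case_pref, ctrl_pref),
                trans=(
                    [s for s in paired.transcriptome.subject_ids if s.startswith("CASE")],
                    [s for s in paired.transcriptome.subject_ids if not s.startswith("CASE")],
                ),
            )

        stage = "crossomics"
        thresholds = co.SelectionThresholds(
            prot_log2fc_min=config.prot_log2fc_min,
            trans_log2fc_min=config.trans_log2fc_min,
            alpha_de=config.alpha_de,
            alpha_corr=config.alpha_corr,
            require_concordant_direction=config.require_concordant_direction,
        )
        de_prot = co.differential_expression(paired.proteome, *de_groups["prot"])
        de_trans = co.differential_expression(paired.transcriptome, *de_groups["trans"])
        corrs = co.pair_correlation(paired)
        candidates = co.select_tumour_derived(de_prot, de_trans, corrs, thresholds, paired.pair_map)
        _write_tsv(de_prot, outdir / "de_proteome.tsv")
        _write_tsv(de_trans, outdir / "de_transcriptome.tsv")
        _write_tsv(corrs, outdir / "pair_correlation.tsv")
        _write_tsv(candidates, outdir / "tumour_derived_candidates.tsv")
        bundle.update(de_prot=de_prot, de_trans=de_trans, corrs=corrs, candidates=candidates)

        stage = "clonality"
        if trans_cl is not None:
            t_scores = clon.score_table(trans_cl).set_index("subject_id")
            p_scores = clon.score_table(prot_cl).set_index("subject_id")
            tests = clon.compare_scores(
                {
                    "case_trans": t_scores.loc[t_scores["group"] == "case", "score"].to_numpy(),
                    "control_trans": t_scores.loc[t_scores["group"] == "control", "score"].to_numpy(),
                },
                [("case_trans", "control_trans")],
            )
            cross = clon.score_cross_layer_correlation(t_scores["score"], p_scores["score"], p_scores["group"])
            mk = marker.set_index("subject_id")
            mkcorr = clon.score_marker_correlation(p_scores["score"], mk["marker"], p_scores["group"])
            _write_tsv(p_scores, outdir / "clonality_scores_proteome.tsv")
            _write_tsv(tests, outdir / "clonality_tests.tsv", index=False)
            _write_tsv(cross, outdir / "clonality_cross_layer.tsv")
            _write_tsv(mkcorr, outdir / "clonality_marker_corr.tsv")
            bundle.update(clonality_tests=tests, clonality_cross=cross, clonality_marker=mkcorr)

        stage = "evaluate+model"
        descriptives = group_tests(cohort)
        age_tab, sex_tab = confounder_screen(cohort)
        delta_per, delta_between = delta_igm_analysis(cohort)
        sv = split_and_validate(
            cohort,
            derivation_fraction=config.derivation_fraction,
            seed=config.seed,
            n_boot=config.n_boot,
            knots=config.knots,
            cutoff_strategy=config.cutoff_strategy,
        )
        res = sv.results
        _write_tsv(descriptives, outdir / "group_tests.tsv", index=False)
        _write_tsv(age_tab, outdir / "confounder_age.tsv", index=False)
        _write_tsv(sex_tab, outdir / "confounder_sex.tsv", index=False)
        _write_tsv(delta_per, outdir / "delta_igm_per_group.tsv", index=False)
        _write_tsv(delta_between, outdir / "delta_igm_between.tsv", index=False)
        _write_tsv(sv.roc_table, outdir / "roc_comparison.tsv", index=False)
        _write_tsv(res.inclusion_report, outdir / "model_inclusion.tsv", index=False)
        _write_tsv(res.fit.summary(), outdir / "model_coefficients.tsv")
        model_json = {
            "cutoffs": dataclasses.asdict(res.cutoffs),
            "age_cutoff_years": res.age_cut,
            "auc_continuous": res.marker_roc.auc,
            "auc_ci": list(res.marker_roc.auc_ci),
            "p_nonlinearity": res.rcs.p_nonlinearity,
            "terms": res.fit.terms,
            "coefficients": res.fit.params,
            "nomogram_points": res.nomogram.points,
            "nomogram_scale": res.nomogram.scale,
            "nomogram_offset": res.nomogram.offset,
        }
        _write_json(model_json, outdir / "diagnostic_model.json")
        calib = res.calibration(n_bins=config.calibration_bins,
                                bootstrap_reps=config.calibration_bootstrap, seed=config.seed)
        _write_tsv(calib, outdir / "calibration.tsv", index=False)
        bundle.update(cohort=cohort, split=sv, results=res, calibration=calib)

        stage = "report"
        write_report_figures(bundle, outdir)
    except Exception as exc:  # noqa: BLE001 - re-raised with the stage name
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    return bundle


def write_report_figures(bundle: dict, outdir: Path) -> list[Path]:
    """ROC, RCS and calibration figures as SVG (non-interactive backend)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    paths = []
    res = bundle.get("results")
    if res is None:
        return paths

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1 - res.marker_roc.specificity, res.marker_roc.sensitivity,
            drawstyle="steps-post", label=f"marker AUC={res.marker_roc.auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False)
    p = outdir / "roc.svg"
    fig.savefig(p, metadata={"Date": None})
    plt.close(fig)
    paths.append(p)

    xs = np.linspace(res.rcs.knots[0], res.rcs.knots[-1], 200)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(xs, res.rcs.predict_logit(xs))
    for k in res.rcs.knots:
        ax.axvline(k, color="grey", lw=0.6, ls=":")
    ax.set_xlabel("marker (g/L)")
    ax.set_ylabel("log-odds of disease")
    ax.set_title(f"p non-linearity = {res.rcs.p_nonlinearity:.3f}")
    p = outdir / "rcs.svg"
    fig.savefig(p, metadata={"Date": None})
    plt.close(fig)
    paths.append(p)

    calib = bundle.get("calibration")
    if calib is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(calib["mean_predicted"], calib["observed"], "o-", label="apparent")
        if "observed_corrected" in calib:
            ax.plot(calib["mean_predicted"], calib["observed_corrected"], "s--", label="optimism-corrected")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("predicted probability")
        ax.set_ylabel("observed frequency")
        ax.legend(frameon=False)
        p = outdir / "calibration.svg"
        fig.savefig(p, metadata={"Date": None})
        plt.close(fig)
        paths.append(p)
    for p in paths:
        log.info("wrote %s", p)
    return paths
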