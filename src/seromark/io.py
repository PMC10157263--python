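"""Tab-separated file dialects and the pipeline configuration.

All tables are TSV (UTF-8, '.' decimal separator): expression matrices are
features x subjects with a header row of subject ids and the feature id in
the first column; the cohort table follows the column dictionary of
:data:`seromark.containers.COHORT_SCHEMA` with ISO-8601 dates.  Readers are
strict: duplicate ids, non-numeric cells, unknown diagnosis classes and
non-g/L unit annotations are errors, never silent coercions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, PairedOmics, validate_cohort

#: immunoglobulin unit accepted in cohort metadata; anything else is rejected
REQUIRED_IGM_UNIT = "g/L"


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", lineterminator="\n")


def read_expression_matrix(path, layer: str) -> ExpressionMatrix:
    """Parse the documented features-x-subjects TSV dialect.

    Duplicate feature/subject ids raise an error naming the id; a
    non-numeric cell raises an error naming the row and column.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        # cell-by-cell float() parsing: exact round-trip (pandas' fast float
        # path can be off by one ulp) and precise error localisation
        for i, cell in enumerate(frame[col]):
            try:
                values[i, j] = float(cell)
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"non-numeric cell at feature {frame.index[i]!r}, subject {col!r}"
                ) from exc
    return ExpressionMatrix(layer, list(frame.index), list(frame.columns), values)


def write_pair_map(pair_map, path) -> None:
    pd.DataFrame(pair_map, columns=["protein_id", "transcript_id", "gene_symbol"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_pair_map(path) -> list[tuple[str, str, str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["protein_id", "transcript_id", "gene_symbol"]
    if list(frame.columns) != expected:
        raise ValueError(f"pair map must have columns {expected}, got {list(frame.columns)}")
    return [tuple(r) for r in frame.itertuples(index=False)]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    if "date_of_diagnosis" in out.columns:
        out["date_of_diagnosis"] = pd.to_datetime(out["date_of_diagnosis"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_cohort(path, igm_unit: str = REQUIRED_IGM_UNIT) -> pd.DataFrame:
    """Read and validate the clinical cohort TSV.

    ``igm_unit`` must be 'g/L'; any other annotation is rejected rather
    than converted.
    """
    if igm_unit != REQUIRED_IGM_UNIT:
        raise ValueError(f"immunoglobulin unit must be {REQUIRED_IGM_UNIT!r}, got {igm_unit!r}")
    frame = pd.read_csv(path, sep="\t")
    return validate_cohort(frame)


def write_truth_sidecar(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclasses.dataclass
class PipelineConfig:
    """Whole-pipeline parameters; round-trips losslessly through YAML."""

    seed: int = 0
    outdir: str = "seromark_out"
    # simulate (None -> read inputs from the paths below instead)
    simulate: bool = True
    omics: dict = dataclasses.field(default_factory=dict)
    cohort_sim: dict = dataclasses.field(default_factory=dict)
    clonality_sim: dict = dataclasses.field(default_factory=dict)
    # external inputs (used when simulate = False)
    proteome_path: str | None = None
    transcriptome_path: str | None = None
    pair_map_path: str | None = None
    cohort_path: str | None = None
    # cross-omics thresholds
    prot_log2fc_min: float = float(np.log2(1.2))
    trans_log2fc_min: float = float(np.log2(1.5))
    alpha_de: float = 0.05
    alpha_corr: float = 0.05
    require_concordant_direction: bool = True
    # biomarker / model
    n_boot: int = 2000
    knots: int = 4
    cutoff_strategy: str = "youden"
    derivation_fraction: float = 0.6
    calibration_bins: int = 10
    calibration_bootstrap: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        p = Path(str(source))
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        payload = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)


def load_paired_omics(config: PipelineConfig) -> PairedOmics:
    """Read the two layers and the pair map named in the config."""
    for attr in ("proteome_path", "transcriptome_path", "pair_map_path"):
        if getattr(config, attr) is None:
            raise ValueError(f"config.{attr} is required when simulate = False")
    prot = read_expression_matrix(config.proteome_path, "proteome")
    trans = read_expression_matrix(config.transcriptome_path, "transcriptome")
    pair_map = read_pair_map(config.pair_map_path)
    shared = [s for s in prot.subject_ids if s in set(trans.subject_ids)]
    return PairedOmics(prot, trans, pair_map, shared)
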