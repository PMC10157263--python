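"""Core in-memory containers for the paired-omics and clinical-cohort data.

An :class:`ExpressionMatrix` holds one omics layer (features x subjects,
non-negative abundances); :class:`PairedOmics` ties a serum-proteome layer to
a tissue-transcriptome layer through a protein<->transcript identifier map.
The clinical cohort is carried as a plain :class:`pandas.DataFrame` validated
against :data:`COHORT_SCHEMA`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTEOME = "proteome"
TRANSCRIPTOME = "transcriptome"

DIAGNOSIS_CLASSES = (
    "EMZL",
    "other_lymphoma",
    "lymphoid_hyperplasia",
    "chronic_inflammation",
)
#: the three non-malignant / non-EMZL classes pooled as "controls"
CONTROL_CLASSES = DIAGNOSIS_CLASSES[1:]

#: column -> (dtype kind, required) for the cohort table.  Optional columns
#: may be absent entirely; required ones must be present and non-null.
COHORT_SCHEMA = {
    "subject_id": ("str", True),
    "diagnosis_class": ("category", True),
    "igm_g_per_l": ("float", True),
    "iga_g_per_l": ("float", False),
    "igg_g_per_l": ("float", False),
    "ige_g_per_l": ("float", False),
    "age_years": ("float", True),
    "sex": ("category", True),
    "date_of_diagnosis": ("date", True),
    "bilateral": ("bool", True),
    "disease_site": ("category", True),
    "lacrimal_involvement": ("bool", True),
    "igm_post_treatment": ("float", False),
    "ki67": ("float", False),
    "ann_arbor": ("category", False),
    "ipi": ("category", False),
}


class CohortSchemaError(ValueError):
    """Raised when a cohort table violates the documented column dictionary."""


@dataclass
class ExpressionMatrix:
    """One omics layer: a features-by-subjects non-negative abundance matrix.

    Parameters
    ----------
    layer : {"proteome", "transcriptome"}
    feature_ids, subject_ids : unique identifier lists
    values : array of shape (n_features, n_subjects), abundances >= 0
    """

    layer: str
    feature_ids: list[str]
    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.subject_ids = list(self.subject_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.layer not in (PROTEOME, TRANSCRIPTOME):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.values.shape != (len(self.feature_ids), len(self.subject_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.subject_ids)} subjects"
            )
        for name, ids in (("feature", self.feature_ids), ("subject", self.subject_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id {dup!r}")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("abundances must be finite and non-negative")
        self._findex = {f: i for i, f in enumerate(self.feature_ids)}
        self._sindex = {s: j for j, s in enumerate(self.subject_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def feature(self, feature_id: str) -> np.ndarray:
        """Abundance vector of one feature across all subjects."""
        return self.values[self._findex[feature_id]]

    def subject_columns(self, subject_ids) -> np.ndarray:
        """Sub-matrix restricted to the given subjects, in the given order."""
        missing = [s for s in subject_ids if s not in self._sindex]
        if missing:
            raise KeyError(f"unknown subject id(s): {missing}")
        cols = [self._sindex[s] for s in subject_ids]
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.subject_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, layer: str) -> "ExpressionMatrix":
        return cls(layer, list(frame.index), list(frame.columns), frame.to_numpy(float))


@dataclass
class PairedOmics:
    """Two omics layers joined by a protein<->transcript identifier map.

    ``pair_map`` rows are ``(protein_id, transcript_id, gene_symbol)``;
    every entry must resolve in both layers.  ``shared_subjects`` lists the
    subjects profiled in both layers — cross-layer correlations are computed
    on this overlap only.
    """

    proteome: ExpressionMatrix
    transcriptome: ExpressionMatrix
    pair_map: list[tuple[str, str, str]]
    shared_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pair_map = [tuple(p) for p in self.pair_map]
        for prot_id, trans_id, _gene in self.pair_map:
            if prot_id not in self.proteome._findex:
                raise ValueError(f"pair_map protein id {prot_id!r} not in proteome")
            if trans_id not in self.transcriptome._findex:
                raise ValueError(f"pair_map transcript id {trans_id!r} not in transcriptome")
        for s in self.shared_subjects:
            if s not in self.proteome._sindex or s not in self.transcriptome._sindex:
                raise ValueError(f"shared subject {s!r} missing from a layer")

    @property
    def gene_symbols(self) -> list[str]:
        return [g for _, _, g in self.pair_map]


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against :data:`COHORT_SCHEMA`.

    Returns a typed copy.  Raises :class:`CohortSchemaError` on a missing
    required column, an unknown diagnosis class, a non-positive IgM, or an
    age outside [0, 120].
    """
    df = df.copy()
    for col, (_kind, required) in COHORT_SCHEMA.items():
        if col not in df.columns:
            if required:
                raise CohortSchemaError(f"missing required column {col!r}")
            continue
    unknown = set(df["diagnosis_class"].astype(str)) - set(DIAGNOSIS_CLASSES)
    if unknown:
        raise CohortSchemaError(f"unknown diagnosis class(es): {sorted(unknown)}")
    df["igm_g_per_l"] = pd.to_numeric(df["igm_g_per_l"])
    if (df["igm_g_per_l"] <= 0).any():
        raise CohortSchemaError("igm_g_per_l must be strictly positive")
    df["age_years"] = pd.to_numeric(df["age_years"])
    if ((df["age_years"] < 0) | (df["age_years"] > 120)).any():
        raise CohortSchemaError("age_years outside [0, 120]")
    dup = _first_duplicate(list(df["subject_id"]))
    if dup is not None:
        raise CohortSchemaError(f"duplicate subject id {dup!r}")
    df["date_of_diagnosis"] = pd.to_datetime(df["date_of_diagnosis"], format="ISO8601")
    for col in ("bilateral", "lacrimal_involvement"):
        df[col] = df[col].astype(bool)
    return df


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None
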