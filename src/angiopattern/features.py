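"""Feature assembly for the pattern classifiers.

Two feature sets are used.  The μFR model takes 12 clinical and
procedural features: six demographic (age, sex, smoking status, diabetes,
dyslipidaemia, hypertension), the three leading MFPCA scores, the
reference vessel diameter, the distal μFR and the maximum dμFR/ds.  The
PPGi model appends PPGi itself as a thirteenth feature.

Categorical encodings are fixed: sex is male = 1; smoking enters as two
indicator contrasts (current, previous) against the non-smoker baseline,
so the encoded design matrix has one more column than the feature count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientCovariates
from .curves import VesselRecord
from .indices import compute_ppgi, max_local_gradient

#: conceptual feature order of the μFR model (smoking is one feature)
FEATURES_MUFR = (
    "age",
    "sex",
    "smoking",
    "diabetes",
    "dyslipidaemia",
    "hypertension",
    "score1",
    "score2",
    "score3",
    "reference_diameter",
    "distal_mufr",
    "d_mufr_ds",
)
FEATURES_PPGI = FEATURES_MUFR + ("ppgi",)

#: encoded design-matrix column order (smoking expanded to two indicators)
ENCODED_COLUMNS_MUFR = (
    "age",
    "sex_male",
    "smoking_current",
    "smoking_previous",
    "diabetes",
    "dyslipidaemia",
    "hypertension",
    "score1",
    "score2",
    "score3",
    "reference_diameter",
    "distal_mufr",
    "d_mufr_ds",
)
ENCODED_COLUMNS_PPGI = ENCODED_COLUMNS_MUFR + ("ppgi",)


class MissingFeatureError(ValueError):
    """A required covariate or curve-derived quantity is absent."""


@dataclass(frozen=True)
class FeatureVector:
    """One vessel's classifier input in the fixed, documented order."""

    age: float
    sex_male: int
    smoking_current: int
    smoking_previous: int
    diabetes: int
    dyslipidaemia: int
    hypertension: int
    score1: float
    score2: float
    score3: float
    reference_diameter: float
    distal_mufr: float
    d_mufr_ds: float
    ppgi: Optional[float] = None

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURES_PPGI if self.ppgi is not None else FEATURES_MUFR

    def encoded(self) -> np.ndarray:
        vals = [
            self.age,
            self.sex_male,
            self.smoking_current,
            self.smoking_previous,
            self.diabetes,
            self.dyslipidaemia,
            self.hypertension,
            self.score1,
            self.score2,
            self.score3,
            self.reference_diameter,
            self.distal_mufr,
            self.d_mufr_ds,
        ]
        if self.ppgi is not None:
            vals.append(self.ppgi)
        return np.array(vals, float)

    def encoded_names(self) -> tuple[str, ...]:
        return ENCODED_COLUMNS_PPGI if self.ppgi is not None else ENCODED_COLUMNS_MUFR


def assemble_features(
    record: VesselRecord,
    covariates: PatientCovariates,
    scores: Sequence[float],
    include_ppgi: bool = False,
) -> FeatureVector:
    """Deterministically map one vessel to its feature vector.

    Raises :class:`MissingFeatureError` on any absent input — imputation
    is never silent.
    """
    if covariates is None:
        raise MissingFeatureError(f"no covariates for vessel {record.vessel_id}")
    scores = list(scores)
    if len(scores) != 3 or any(s is None or not np.isfinite(s) for s in scores):
        raise MissingFeatureError("exactly three finite MFPCA scores are required")
    for field_name in ("age", "sex", "smoking", "diabetes", "dyslipidaemia", "hypertension"):
        if getattr(covariates, field_name) is None:
            raise MissingFeatureError(f"covariate {field_name!r} is missing")
    ppgi = compute_ppgi(record.curve).ppgi if include_ppgi else None
    return FeatureVector(
        age=float(covariates.age),
        sex_male=int(covariates.sex == "male"),
        smoking_current=int(covariates.smoking == "current"),
        smoking_previous=int(covariates.smoking == "previous"),
        diabetes=int(covariates.diabetes),
        dyslipidaemia=int(covariates.dyslipidaemia),
        hypertension=int(covariates.hypertension),
        score1=float(scores[0]),
        score2=float(scores[1]),
        score3=float(scores[2]),
        reference_diameter=float(record.reference_diameter),
        distal_mufr=float(record.distal_mufr),
        d_mufr_ds=max_local_gradient(record.curve),
        ppgi=ppgi,
    )


def build_feature_frame(
    records: Sequence[VesselRecord],
    covariates_by_patient: dict[str, PatientCovariates],
    scores: np.ndarray,
    include_ppgi: bool = False,
) -> pd.DataFrame:
    """Encoded design matrix (one row per vessel, indexed by vessel_id)."""
    rows, index = [], []
    for rec, sc in zip(records, scores):
        fv = assemble_features(rec, covariates_by_patient.get(rec.patient_id), sc, include_ppgi)
        rows.append(fv.encoded())
        index.append(rec.vessel_id)
    cols = ENCODED_COLUMNS_PPGI if include_ppgi else ENCODED_COLUMNS_MUFR
    return pd.DataFrame(rows, index=index, columns=list(cols))
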