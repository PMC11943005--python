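"""Respondent data model, differentiated expertise weights, and sample-size arithmetic.

Healthcare-professional survey respondents are weighted by three ordinal
credentials — education level, years of specialty experience, and role held
during the pandemic response — so that answers from more senior or more
exposed professionals count for more in the downstream Likert aggregation.
Each credential maps to a fixed coefficient; the three coefficients combine
into a single composite weight per respondent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EducationLevel",
    "ExperienceBand",
    "PandemicRole",
    "Profession",
    "Sector",
    "WeightMap",
    "Respondent",
    "RespondentWeights",
    "LikertItem",
    "DEFAULT_WEIGHT_MAP",
    "assign_respondent_weights",
    "composite_weight",
    "cochran_sample_size",
    "read_respondents",
    "RespondentWeigher",
]


class EducationLevel(str, Enum):
    health_assistant = "health_assistant"
    medical_assistant = "medical_assistant"
    resident = "resident"
    specialist_or_pharmacist = "specialist_or_pharmacist"
    primary_doctor_or_pharmacist = "primary_doctor_or_pharmacist"
    phd_academic = "phd_academic"


class ExperienceBand(str, Enum):
    y0_4 = "0-4"
    y5_9 = "5-9"
    y10_14 = "10-14"
    y15_19 = "15-19"
    y20_plus = "20+"


class PandemicRole(str, Enum):
    not_involved_or_education = "not_involved_or_education"
    dsp_ministry_pharmacy_ngo = "dsp_ministry_pharmacy_ngo"
    triage_or_vaccination = "triage_or_vaccination"
    civil_hospital = "civil_hospital"
    covid_support_hospital_er_ambulance = "covid_support_hospital_er_ambulance"


class Profession(str, Enum):
    doctor = "doctor"
    pharmacist = "pharmacist"
    medical_assistant = "medical_assistant"


class Sector(str, Enum):
    private = "private"
    civil = "civil"
    public_order_security = "public_order_security"


class CompositeScheme(str, Enum):
    mean = "mean"
    product = "product"
    sum = "sum"


@dataclass(frozen=True)
class WeightMap:
    """Total maps from demographic category to weight coefficient.

    Every enum category must appear exactly once in its map; lookups of
    unmapped categories raise ``KeyError`` at assignment time rather than
    defaulting, so a misconfigured map can never silently flatten the
    weighting scheme.
    """

    education: Mapping[str, float]
    experience: Mapping[str, float]
    role: Mapping[str, float]
    scheme: CompositeScheme = CompositeScheme.mean

    def __post_init__(self) -> None:
        for name, mapping, enum in (
            ("education", self.education, EducationLevel),
            ("experience", self.experience, ExperienceBand),
            ("role", self.role, PandemicRole),
        ):
            missing = {e.value for e in enum} - set(mapping)
            if missing:
                raise ValueError(f"weight map '{name}' is not total; missing {sorted(missing)}")


#: Coefficients elicited for the Romanian healthcare-professional survey:
#: education spans 1–3.5 (health assistant → PhD/academic), experience and
#: pandemic role span 1–3.
DEFAULT_WEIGHT_MAP = WeightMap(
    education={
        "health_assistant": 1.0,
        "medical_assistant": 1.5,
        "resident": 2.0,
        "specialist_or_pharmacist": 2.5,
        "primary_doctor_or_pharmacist": 3.0,
        "phd_academic": 3.5,
    },
    experience={"0-4": 1.0, "5-9": 1.5, "10-14": 2.0, "15-19": 2.5, "20+": 3.0},
    role={
        "not_involved_or_education": 1.0,
        "dsp_ministry_pharmacy_ngo": 1.5,
        "triage_or_vaccination": 2.0,
        "civil_hospital": 2.5,
        "covid_support_hospital_er_ambulance": 3.0,
    },
)


@dataclass(frozen=True)
class Respondent:
    """One survey respondent; categorical fields use the enum token strings."""

    id: str
    education_level: str
    experience_band: str
    pandemic_role: str
    profession: str | None = None
    sector: str | None = None
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        _require_member(EducationLevel, self.education_level, "education_level")
        _require_member(ExperienceBand, self.experience_band, "experience_band")
        _require_member(PandemicRole, self.pandemic_role, "pandemic_role")
        if self.profession is not None:
            _require_member(Profession, self.profession, "profession")
        if self.sector is not None:
            _require_member(Sector, self.sector, "sector")


@dataclass(frozen=True)
class RespondentWeights:
    w_edu: float
    w_exp: float
    w_role: float
    composite: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.w_edu <= 3.5):
            raise ValueError(f"w_edu {self.w_edu} outside [1, 3.5]")
        if not (1.0 <= self.w_exp <= 3.0):
            raise ValueError(f"w_exp {self.w_exp} outside [1, 3]")
        if not (1.0 <= self.w_role <= 3.0):
            raise ValueError(f"w_role {self.w_role} outside [1, 3]")
        if self.composite <= 0:
            raise ValueError("composite weight must be positive")


@dataclass(frozen=True)
class LikertItem:
    """Metadata for one Likert-scale question (1–5 or 1–6 in this survey)."""

    item_id: str
    scale_min: int = 1
    scale_max: int = 5
    anchor_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError(f"{self.item_id}: scale_min must be < scale_max")

    @property
    def scale_points(self) -> np.ndarray:
        return np.arange(self.scale_min, self.scale_max + 1)


def _require_member(enum: type[Enum], value: str, field: str) -> None:
    valid = {e.value for e in enum}
    if value not in valid:
        raise ValueError(f"unknown {field} category {value!r}; expected one of {sorted(valid)}")


def composite_weight(
    w_edu: float, w_exp: float, w_role: float, scheme: str | CompositeScheme = "mean"
) -> float:
    """Combine the three credential coefficients into one respondent weight.

    ``mean`` (default) keeps the composite on the 1–3.5 coefficient scale;
    ``product`` and ``sum`` are available for sensitivity checks.
    """
    scheme = CompositeScheme(scheme)
    if scheme is CompositeScheme.mean:
        return (w_edu + w_exp + w_role) / 3.0
    if scheme is CompositeScheme.product:
        return w_edu * w_exp * w_role
    return w_edu + w_exp + w_role


def assign_respondent_weights(
    r: Respondent, weight_map: WeightMap = DEFAULT_WEIGHT_MAP
) -> RespondentWeights:
    """Look up the three coefficients for one respondent and combine them.

    Raises ``KeyError`` naming the offending field if a category is not in
    the map (maps are validated total at construction, so this only fires
    for custom partial mappings).
    """
    try:
        w_edu = weight_map.education[r.education_level]
    except KeyError:
        raise KeyError(f"education_level {r.education_level!r} not in weight map") from None
    try:
        w_exp = weight_map.experience[r.experience_band]
    except KeyError:
        raise KeyError(f"experience_band {r.experience_band!r} not in weight map") from None
    try:
        w_role = weight_map.role[r.pandemic_role]
    except KeyError:
        raise KeyError(f"pandemic_role {r.pandemic_role!r} not in weight map") from None
    return RespondentWeights(
        w_edu=w_edu,
        w_exp=w_exp,
        w_role=w_role,
        composite=composite_weight(w_edu, w_exp, w_role, weight_map.scheme),
    )


def cochran_sample_size(z: float, p: float, e: float) -> int:
    """Minimum sample size for a large population: floor(z²·p·(1−p)/e²).

    The dispersion p·(1−p) is maximal (0.25) at p = 0.5, the conventional
    worst case when the phenomenon's incidence is unknown. At z = 1.96
    (95% confidence), p = 0.5 and e = 0.05 this gives 384.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if e <= 0:
        raise ValueError(f"margin of error must be positive, got {e}")
    if z <= 0:
        raise ValueError(f"z must be positive, got {z}")
    return math.floor(z * z * p * (1.0 - p) / (e * e))


_REQUIRED_COLUMNS = ("id", "education_level", "experience_band", "pandemic_role")


def read_respondents(path: str | Path) -> pd.DataFrame:
    """Read a respondent table from CSV, validating every categorical token.

    Missing markers '' / 'NA' are allowed only in the optional columns
    (profession, sector, age, sex); an unknown token in any categorical
    column is a hard load-time error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"respondent CSV missing required columns {sorted(missing_cols)}")
    df = df.replace({"": None, "NA": None})
    validate_respondent_frame(df)
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"])
    return df


def validate_respondent_frame(df: pd.DataFrame) -> None:
    """Check every categorical column of a respondent frame against its enum."""
    checks = [
        ("education_level", EducationLevel, True),
        ("experience_band", ExperienceBand, True),
        ("pandemic_role", PandemicRole, True),
        ("profession", Profession, False),
        ("sector", Sector, False),
    ]
    for col, enum, required in checks:
        if col not in df.columns:
            if required:
                raise ValueError(f"respondent table missing required column {col!r}")
            continue
        values = df[col]
        if required and values.isna().any():
            bad = df.index[values.isna()][0]
            raise ValueError(f"missing {col} for respondent at row {bad}")
        valid = {e.value for e in enum}
        unknown = set(values.dropna()) - valid
        if unknown:
            raise ValueError(
                f"unknown {col} categories {sorted(unknown)}; expected one of {sorted(valid)}"
            )


class RespondentWeigher(BaseEstimator, TransformerMixin):
    """Transformer mapping a respondent table to composite expertise weights.

    Parameters
    ----------
    weight_map : WeightMap, default: the packaged survey coefficients
        Category-to-coefficient maps for education, experience and role.
    scheme : {"mean", "product", "sum"}, default "mean"
        How the three coefficients combine; overrides the map's scheme.

    After ``fit``, ``weights_`` holds the composite weight per row of the
    fitted frame. ``transform`` returns the composite weights of its input
    as a 1-D float array.
    """

    def __init__(self, weight_map: WeightMap | None = None, scheme: str = "mean"):
        self.weight_map = weight_map
        self.scheme = scheme

    def _resolved_map(self) -> WeightMap:
        base = self.weight_map if self.weight_map is not None else DEFAULT_WEIGHT_MAP
        return WeightMap(
            education=base.education,
            experience=base.experience,
            role=base.role,
            scheme=CompositeScheme(self.scheme),
        )

    def fit(self, X: pd.DataFrame, y=None) -> "RespondentWeigher":
        self.weights_ = self.transform(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("RespondentWeigher expects a pandas DataFrame of respondents")
        validate_respondent_frame(X)
        wm = self._resolved_map()
        out = np.empty(len(X), dtype=float)
        for i, (_, row) in enumerate(X.iterrows()):
            w_edu = wm.education[row["education_level"]]
            w_exp = wm.experience[row["experience_band"]]
            w_role = wm.role[row["pandemic_role"]]
            out[i] = composite_weight(w_edu, w_exp, w_role, wm.scheme)
        return out
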