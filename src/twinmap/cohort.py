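"""Cohort ingestion, eligibility filtering and predictor encoding.

The cohort is carried as a :class:`pandas.DataFrame` with one row per
patient and a canonical column set (see :data:`RAW_COLUMNS`).  Patients are
women aged 70+ with HER2-negative early breast cancer; the analysis outcome
is overall survival at 5 years, and nine pre-treatment predictors feed every
downstream stage: age, tumor size (mm), SBR grade (binarized low 1-2 vs
high 3), number of involved lymph nodes, hormone-receptor status (positive
when ER or PR staining reaches 10% of tumor cells), hemoglobin (g/dL),
lymphocyte count (G/L), BMI and presence of comorbidity.  Treatment fields
are deliberately excluded from the predictor vector.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    EmptyInputError,
    IncompleteRecordError,
    SchemaError,
)

#: canonical raw columns of a patient table
RAW_COLUMNS = [
    "patient_id",
    "age",
    "bmi",
    "tumor_size",
    "sbr_grade",
    "n_nodes_involved",
    "er_percent",
    "pr_percent",
    "hr_positive",
    "hemoglobin",
    "lymphocytes",
    "has_comorbidity",
    "received_chemo",
    "followup_months",
    "death",
    "relapse",
]

#: the 9 predictors, in canonical order
PREDICTOR_COLUMNS = [
    "age",
    "tumor_size",
    "grade_high",
    "n_nodes",
    "hr_positive",
    "hemoglobin",
    "lymphocytes",
    "bmi",
    "comorbidity",
]

#: raw fields that must be non-missing for a complete case (hormone-receptor
#: status may come either as er/pr percentages or as a precomputed flag)
_PREDICTOR_SOURCES = [
    "age",
    "tumor_size",
    "sbr_grade",
    "n_nodes_involved",
    "hemoglobin",
    "lymphocytes",
    "bmi",
    "has_comorbidity",
]

_MANDATORY = _PREDICTOR_SOURCES + ["followup_months", "death"]

#: accepted missing-value spellings on read (case-insensitive)
NA_MARKERS = ["", "na", "nan", "NA", "NaN", "NAN", "Na"]

#: age bins of the cohort summary: 70-74, 75-79, 80-84, 85-89, >90 (the
#: open top bin is treated as 90-94 for the grouped median)
AGE_BIN_EDGES = [70, 75, 80, 85, 90, np.inf]
AGE_BIN_STARTS = [70, 75, 80, 85, 90]
AGE_BIN_LABELS = ["70-74", "75-79", "80-84", "85-89", ">90"]

#: months in the 5-year horizon; death at exactly 60 months counts as a
#: 5-year death (closed boundary)
FIVE_YEARS = 60.0

_BOOL_MAP = {
    "true": True, "false": False, "yes": True, "no": False,
    "1": True, "0": False, "1.0": True, "0.0": False,
    "t": True, "f": False, "y": True, "n": False,
}


@dataclass
class CohortSummary:
    """Table-1-style description of a cohort."""

    n_total: int
    n_complete: int
    age_bin_counts: dict[str, int]
    grouped_median_age: int
    pct_chemo: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _coerce_bool(series: pd.Series) -> pd.Series:
    """Map common boolean spellings to True/False, anything else to NA."""
    if series.dtype == bool:
        return series.astype(object)

    def one(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, float, np.integer, np.floating)):
            return bool(v) if v in (0, 1) else pd.NA
        return _BOOL_MAP.get(str(v).strip().lower(), pd.NA)

    return series.map(one)


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
    require_outcome: bool = True,
) -> pd.DataFrame:
    """Read a delimited patient table into the canonical cohort frame.

    Parameters
    ----------
    path : path to a delimited text file with a header row.
    schema : optional map of *file column name -> canonical name*; columns
        not mentioned are matched by name.  Declaring ``hr_positive``
        (instead of ``er_percent``/``pr_percent``) signals that receptor
        status arrives as a precomputed flag.
    sep : field delimiter, comma by default.
    require_outcome : when False, follow-up and vital-status columns are
        optional (for query-patient files without resolved outcomes).

    Unparseable cells become missing values; the row count of the file is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep, na_values=NA_MARKERS, keep_default_na=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no data rows in {path}") from None
    if df.empty:
        raise EmptyInputError(f"no data rows in {path}")

    if schema:
        df = df.rename(columns=dict(schema))

    has_flag = "hr_positive" in df.columns
    has_pct = "er_percent" in df.columns and "pr_percent" in df.columns
    if not (has_flag or has_pct):
        raise SchemaError(
            "missing mandatory column: er_percent/pr_percent (or hr_positive)"
        )
    mandatory = _MANDATORY if require_outcome else _PREDICTOR_SOURCES
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")

    for col in RAW_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA

    numeric = ["age", "bmi", "tumor_size", "sbr_grade", "n_nodes_involved",
               "er_percent", "pr_percent", "hemoglobin", "lymphocytes",
               "followup_months"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ["has_comorbidity", "received_chemo", "death", "relapse",
                "hr_positive"]:
        df[col] = _coerce_bool(df[col])
    if df["patient_id"].isna().all():
        df["patient_id"] = [f"P{i:05d}" for i in range(len(df))]
    return df.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a cohort frame back as delimited text."""
    df.to_csv(path, sep=sep, index=False)


def eligibility_filter(df: pd.DataFrame) -> pd.DataFrame:
    """Retain patients whose 5-year outcome is resolvable.

    A patient is eligible when aged 70 or older at diagnosis and either
    followed for at least 60 months or known to have died (death resolves
    the 5-year outcome regardless of follow-up length).  Order is
    preserved; the filter is idempotent.
    """
    age = pd.to_numeric(df["age"], errors="coerce")
    fup = pd.to_numeric(df["followup_months"], errors="coerce")
    death = df["death"].astype("boolean").fillna(False).astype(bool)
    mask = (age >= 70) & ((fup >= FIVE_YEARS) | death) & fup.notna()
    return df.loc[mask.fillna(False)].reset_index(drop=True)


def _hr_source_complete(df: pd.DataFrame) -> pd.Series:
    pct = df["er_percent"].notna() & df["pr_percent"].notna()
    flag = df["hr_positive"].notna()
    return pct | flag


def complete_case_filter(df: pd.DataFrame) -> pd.DataFrame:
    """Retain records with all 9 predictor source fields non-missing.

    Treatment and outcome fields are not predictors and may stay missing.
    """
    mask = _hr_source_complete(df)
    for col in _PREDICTOR_SOURCES:
        mask &= df[col].notna()
    return df.loc[mask].reset_index(drop=True)


def derive_hr_status(er_percent: float, pr_percent: float) -> int:
    """Hormone-receptor status: positive (1) when ER or PR staining is
    present in at least 10% of tumor cells, else triple negative (0) in
    this HER2-negative setting."""
    for name, v in (("er_percent", er_percent), ("pr_percent", pr_percent)):
        if not 0 <= v <= 100:
            raise DomainError(f"{name}={v!r} outside [0, 100]")
    return int(er_percent >= 10 or pr_percent >= 10)


def binarize_grade(sbr: int) -> int:
    """SBR histological grade binarized: low (1-2) -> 0, high (3) -> 1."""
    if sbr not in (1, 2, 3):
        raise DomainError(f"sbr_grade={sbr!r} not in {{1, 2, 3}}")
    return int(sbr == 3)


def to_predictor_vectors(df: pd.DataFrame) -> pd.DataFrame:
    """Encode complete-case records into the 9-predictor design matrix.

    Columns follow :data:`PREDICTOR_COLUMNS`.  Raises
    :class:`IncompleteRecordError` if any required source field is missing.
    """
    missing = ~(_hr_source_complete(df))
    for col in _PREDICTOR_SOURCES:
        missing |= df[col].isna()
    if missing.any():
        idx = df.index[missing][0]
        raise IncompleteRecordError(
            f"record {df.loc[idx, 'patient_id']!r} has missing predictor fields"
        )

    hr = df["hr_positive"].copy()
    need = hr.isna()
    if need.any():
        hr.loc[need] = [
            derive_hr_status(er, pr)
            for er, pr in zip(df.loc[need, "er_percent"], df.loc[need, "pr_percent"])
        ]
    grade = df["sbr_grade"].map(lambda s: binarize_grade(int(s)))

    X = pd.DataFrame(
        {
            "age": df["age"].astype(float),
            "tumor_size": df["tumor_size"].astype(float),
            "grade_high": grade.astype(float),
            "n_nodes": df["n_nodes_involved"].astype(float),
            "hr_positive": hr.astype(float),
            "hemoglobin": df["hemoglobin"].astype(float),
            "lymphocytes": df["lymphocytes"].astype(float),
            "bmi": df["bmi"].astype(float),
            "comorbidity": df["has_comorbidity"].astype(float),
        },
        index=df.index,
    )
    return X[PREDICTOR_COLUMNS]


def to_predictor_vector(record: pd.Series) -> np.ndarray:
    """Encode a single patient row; see :func:`to_predictor_vectors`."""
    return to_predictor_vectors(record.to_frame().T).to_numpy()[0]


def resolve_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Attach the 5-year outcome columns.

    ``survived_5y`` is False exactly when death occurred within 60 months
    of diagnosis (closed boundary).  ``in_reference_class`` additionally
    requires remission without relapse by last follow-up; a missing relapse
    flag is treated as relapse-free.
    """
    out = df.copy()
    death = df["death"].astype("boolean").fillna(False).astype(bool)
    fup = pd.to_numeric(df["followup_months"], errors="coerce")
    died_5y = death & (fup <= FIVE_YEARS)
    relapse = df["relapse"].astype("boolean").fillna(False).astype(bool)
    out["survived_5y"] = ~died_5y
    out["in_reference_class"] = out["survived_5y"] & ~relapse
    return out


def grouped_median(bin_counts: Sequence[int], bin_starts: Sequence[float],
                   width: float = 5.0) -> float:
    """Grouped median by linear interpolation within the median bin.

    Uses the classical L + ((N/2 - F)/f)*w formula with the lower real
    class boundary L = bin start - 0.5.
    """
    counts = np.asarray(bin_counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise EmptyInputError("no counts for grouped median")
    half = n / 2.0
    cum = np.cumsum(counts)
    j = int(np.searchsorted(cum, half))
    f_below = cum[j - 1] if j > 0 else 0.0
    lower = bin_starts[j] - 0.5
    return lower + (half - f_below) / counts[j] * width


def summarize_cohort(df: pd.DataFrame) -> CohortSummary:
    """Table-1-style summary: age-bin counts, grouped median age (the
    open >90 bin is treated as 90-94) and rounded chemotherapy percentage."""
    if df.empty:
        raise EmptyInputError("cannot summarize an empty cohort")
    age = pd.to_numeric(df["age"], errors="coerce").dropna()
    counts = pd.cut(
        age, bins=AGE_BIN_EDGES, labels=AGE_BIN_LABELS, right=False
    ).value_counts().reindex(AGE_BIN_LABELS).fillna(0).astype(int)
    gm = grouped_median(counts.to_numpy(), AGE_BIN_STARTS)
    chemo = df["received_chemo"].astype("boolean").fillna(False).astype(bool).sum()
    return CohortSummary(
        n_total=int(len(df)),
        n_complete=int(len(complete_case_filter(df))),
        age_bin_counts=counts.to_dict(),
        grouped_median_age=int(round(gm)),
        pct_chemo=int(round(100.0 * chemo / len(df))),
    )
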