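"""Digital-twin deviation scoring against a good-outcome reference group.

The calibration idea: patients who survived 5 years in remission form a
reference population of favorable trajectories.  Every patient (reference
or not) is then re-expressed as a standardized deviation from their
"digital twins" — the reference profiles most similar to them.  Robust
per-predictor standardization (median center, IQR-based scale) is learned
on the reference group only, so the representation is calibrated to the
favorable-outcome population and is equivariant under affine rescaling of
any raw predictor.

By default the twin neighborhood is the entire reference group, so the
deviation measures each patient's offset from the reference-population
norm — the representation that downstream manifold stratification relies
on to keep between-profile structure.  A finite ``k_twins`` restricts the
neighborhood to the k nearest reference rows, yielding a local contrast
("how do I differ from the favorable patients who look most like me?")
useful for individual-level inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import resolve_outcomes
from .exceptions import CalibrationError, NotFittedError, SplitError

#: IQR-to-standard-deviation conversion for a normal distribution
_IQR_TO_SD = 1.349
#: floor on the robust scale, applied to constant predictors
SCALE_FLOOR = 1e-6


def select_reference(df: pd.DataFrame) -> pd.DataFrame:
    """Reference-class patients: alive at 5 years and relapse-free by the
    last follow-up."""
    out = resolve_outcomes(df)
    return df.loc[out["in_reference_class"].to_numpy(bool)].reset_index(drop=True)


def split_reference_model(
    df: pd.DataFrame, fraction: float = 0.5, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into calibration (reference) and model data.

    A seeded random ``fraction`` of the reference-eligible patients becomes
    the reference group; *all* remaining patients (unselected eligibles plus
    ineligibles) form the model data.  The two parts are disjoint and their
    union is the input, which prevents calibration data from leaking into
    the modelled population.
    """
    out = resolve_outcomes(df)
    eligible = np.flatnonzero(out["in_reference_class"].to_numpy(bool))
    if eligible.size < 2:
        raise SplitError(
            f"only {eligible.size} reference-eligible patients; need at least 2"
        )
    rng = np.random.default_rng(seed)
    n_ref = int(round(fraction * eligible.size))
    ref_idx = np.sort(rng.choice(eligible, size=n_ref, replace=False))
    mask = np.zeros(len(df), dtype=bool)
    mask[ref_idx] = True
    return (
        df.loc[mask].reset_index(drop=True),
        df.loc[~mask].reset_index(drop=True),
    )


class TwinScorer(BaseEstimator, TransformerMixin):
    """Robust standardization + digital-twin neighborhood deviation.

    Parameters
    ----------
    k_twins : int or None, default None
        Size of the digital-twin neighborhood.  ``None`` uses the whole
        reference group (deviation from the reference-population centroid);
        an integer k uses the k nearest standardized reference rows in
        Euclidean distance, ties broken by reference row order.

    Attributes
    ----------
    center_ : (p,) per-predictor median of the reference group.
    scale_ : (p,) per-predictor IQR/1.349, floored at 1e-6.
    reference_ : (n_ref, p) standardized reference matrix.
    """

    def __init__(self, k_twins: int | None = None):
        self.k_twins = k_twins

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("reference must be a 2D predictor matrix")
        k = self.k_twins
        min_rows = (k + 1) if k is not None else 2
        if X.shape[0] < min_rows:
            raise CalibrationError(
                f"reference has {X.shape[0]} rows; need at least {min_rows} "
                f"for k_twins={k}"
            )
        if not np.isfinite(X).all():
            raise CalibrationError("reference matrix contains non-finite values")
        q25, q50, q75 = np.percentile(X, [25, 50, 75], axis=0)
        self.center_ = q50
        scale = (q75 - q25) / _IQR_TO_SD
        # skewed binary predictors have IQR 0 without being constant; fall
        # back to the standard deviation, then to the floor
        zero = scale <= 0
        if zero.any():
            scale[zero] = X.std(axis=0, ddof=1)[zero]
        self.scale_ = np.maximum(scale, SCALE_FLOOR)
        self.reference_ = (X - self.center_) / self.scale_
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "reference_"):
            raise NotFittedError("TwinScorer is not fitted")

    def standardize(self, X) -> np.ndarray:
        """Map raw predictor rows into the reference-calibrated z-space."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.center_) / self.scale_

    def transform(self, X) -> np.ndarray:
        """Deviation vectors: standardized rows minus their twin-neighborhood
        componentwise mean.  Deterministic given the fitted model."""
        self._check_fitted()
        Z = self.standardize(X)
        if Z.shape[0] == 0:
            return Z.copy()
        if self.k_twins is None:
            return Z - self.reference_.mean(axis=0)
        dev = np.empty_like(Z)
        for i, z in enumerate(Z):
            d = np.linalg.norm(self.reference_ - z, axis=1)
            order = np.argsort(d, kind="stable")[: self.k_twins]
            dev[i] = z - self.reference_[order].mean(axis=0)
        return dev

    def twin_indices(self, x) -> np.ndarray:
        """Indices of the digital twins of one patient in the reference."""
        self._check_fitted()
        z = self.standardize(x)[0]
        d = np.linalg.norm(self.reference_ - z, axis=1)
        k = self.k_twins if self.k_twins is not None else len(self.reference_)
        return np.argsort(d, kind="stable")[:k]

    # ---- persistence -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        self._check_fitted()
        payload = {
            "schema": "twinmap.reference_model/1",
            "k_twins": self.k_twins,
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "reference": self.reference_.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TwinScorer":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        if payload.get("schema") != "twinmap.reference_model/1":
            raise ValueError("unrecognized reference-model schema")
        model = cls(k_twins=payload["k_twins"])
        model.center_ = np.asarray(payload["center"], dtype=float)
        model.scale_ = np.asarray(payload["scale"], dtype=float)
        model.reference_ = np.asarray(payload["reference"], dtype=float)
        model.n_features_in_ = model.reference_.shape[1]
        return model


def fit_reference(reference_X, k_twins: int | None = None) -> TwinScorer:
    """Calibrate a :class:`TwinScorer` on the reference predictor matrix."""
    return TwinScorer(k_twins=k_twins).fit(reference_X)


def twin_score(patient, model: TwinScorer) -> np.ndarray:
    """Deviation vector of a single patient (9-vector in, 9-vector out)."""
    return model.transform(np.atleast_2d(patient))[0]


def score_cohort(patients, model: TwinScorer) -> np.ndarray:
    """Rowwise :func:`twin_score`, order preserved."""
    X = np.asarray(patients, dtype=float)
    if X.size == 0:
        return np.empty((0, model.n_features_in_))
    return model.transform(X)
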