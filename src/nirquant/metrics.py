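"""Regression evaluation statistics and RPD quality banding.

With E the existing (reference) values and P the predictions:

    R^2  = 1 - sum((E - P)^2) / sum((E - Ebar)^2)
    RMSE = sqrt(mean((E - P)^2))
    Bias = mean(E - P)                 (signed: existing minus predicted)
    RPD  = 1 / sqrt(1 - R^2)

The RPD quality bands used in grain-composition chemometrics: below 3.0 the
model is poor/unreliable, 3.1-4.9 fair (screening), 5.0-6.4 good (quality
control), 6.5-8.0 very good (process control), above 8.1 excellent for any
quantitative application. Values falling in the printed gaps (e.g. 3.05) are
assigned to the lower band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DimensionError, DomainError

BANDS = ("poor", "fair", "good", "very_good", "excellent")

#: lower edge of each band above "poor"; gap values fall to the band below
_BAND_EDGES = (("excellent", 8.1), ("very_good", 6.5), ("good", 5.0), ("fair", 3.1))


def _paired(existing, predicted, min_len=1):
    e = np.asarray(existing, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if e.size != p.size:
        raise DimensionError(f"length mismatch: {e.size} existing vs {p.size} predicted")
    if e.size < min_len:
        raise DomainError(f"need at least {min_len} points")
    return e, p


def r2(existing, predicted) -> float:
    """Coefficient of determination; negative for worse-than-mean predictors."""
    e, p = _paired(existing, predicted, min_len=2)
    ss_tot = np.sum((e - e.mean()) ** 2)
    if ss_tot < 1e-300:
        raise DegenerateInputError("existing values are constant: R^2 undefined")
    return float(1.0 - np.sum((e - p) ** 2) / ss_tot)


def rmse(existing, predicted) -> float:
    e, p = _paired(existing, predicted)
    return float(np.sqrt(np.mean((e - p) ** 2)))


def bias(existing, predicted) -> float:
    """Mean of (existing - predicted): positive when the model under-predicts."""
    e, p = _paired(existing, predicted)
    return float(np.mean(e - p))


def rpd_from_r2(r2_value: float) -> float:
    """RPD = 1/sqrt(1 - R^2); strictly increasing on [0, 1), equal to 1 at 0."""
    if r2_value >= 1.0:
        raise DomainError("R^2 >= 1 gives an infinite RPD")
    return float(1.0 / np.sqrt(1.0 - r2_value))


def classify_rpd(rpd: float) -> str:
    """Quality band for an RPD value (gap values go to the lower band)."""
    if rpd <= 0:
        raise DomainError("RPD must be positive")
    for band, edge in _BAND_EDGES:
        if rpd > edge if band == "excellent" else rpd >= edge:
            return band
    return "poor"


@dataclass(frozen=True)
class RegressionMetrics:
    """The four evaluation statistics plus the RPD quality band."""

    r2: float
    rmse: float
    bias: float
    rpd: float
    n: int
    band: str

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "bias": self.bias,
                "rpd": self.rpd, "n": self.n, "band": self.band}


def compute_metrics(existing, predicted) -> RegressionMetrics:
    """All four statistics on one (existing, predicted) pair.

    RPD is computed from the unrounded R^2. A perfect predictor (R^2 = 1)
    reports an infinite RPD and the "excellent" band by convention.
    """
    e, p = _paired(existing, predicted, min_len=2)
    r2_val = r2(e, p)
    if r2_val >= 1.0:
        rpd_val, band = float("inf"), "excellent"
    else:
        rpd_val = rpd_from_r2(r2_val)
        band = classify_rpd(rpd_val)
    return RegressionMetrics(r2=r2_val, rmse=rmse(e, p), bias=bias(e, p),
                             rpd=rpd_val, n=int(e.size), band=band)


def evaluate(trained, dataset, indices=None) -> RegressionMetrics:
    """Evaluate a trained regressor on (a selection of) a dataset.

    ``trained`` is anything with a ``predict(X) -> y`` method; ``dataset`` is
    a SpectralDataset (already preprocessed the way the model was trained) or
    an (X, y) tuple.
    """
    if isinstance(dataset, tuple):
        X, y = dataset
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
    else:
        X, y = dataset.X, dataset.y
    if indices is not None:
        idx = np.asarray(indices, dtype=int)
        X, y = X[idx], y[idx]
    if y.size == 0:
        raise DomainError("empty selection")
    return compute_metrics(y, trained.predict(X))


def metrics_table(rows: dict) -> pd.DataFrame:
    """Assemble the per-regressor report table.

    ``rows`` maps regressor name -> dict with keys ``epoch``, ``train``
    (RegressionMetrics), ``test`` (RegressionMetrics). Columns follow the
    conventional layout: training R^2/RMSE/Bias, testing R^2/RMSE/Bias/RPD,
    plus the quality band.
    """
    recs = []
    for name, r in rows.items():
        tr, te = r["train"], r["test"]
        recs.append({
            "Regressor": name, "Epoch": r.get("epoch"),
            "Train R2": tr.r2, "Train RMSE": tr.rmse, "Train Bias": tr.bias,
            "Test R2": te.r2, "Test RMSE": te.rmse, "Test Bias": te.bias,
            "Test RPD": te.rpd, "Band": te.band,
        })
    return pd.DataFrame.from_records(recs)
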