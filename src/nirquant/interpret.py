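"""Perturbation-based regression coefficients for trained networks.

A trained network f maps an SNV-scaled spectrum x to a percent prediction.
Its per-wavelength sensitivity on spectrum x_i is the one-at-a-time forward
finite difference

    w_i[j] = (f(x_i + eps * e_j) - f(x_i)) / eps

and the network's "regression coefficient" profile is the element-wise mean
w_bar of w_i over all training spectra. Important wavelengths are those with
w_bar above ``fraction * max(w_bar)`` or below ``fraction * min(w_bar)``
(signed cutoffs, default fraction 0.50); contiguous selected grid runs are
merged and reported in both nm and cm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axes import INV_CM, NM, SpectralAxis
from .errors import DegenerateInputError, DomainError, PrecisionWarning

DEFAULT_EPSILON = 1e-6


def per_spectrum_weights(trained, x, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Finite-difference weight vector for one spectrum.

    All m perturbed copies are evaluated in a single batched forward pass.
    Emits PrecisionWarning if every difference is exactly zero at this
    epsilon (step below the model's numeric resolution, or a constant model).
    """
    if epsilon <= 0:
        raise DomainError("epsilon must be positive")
    x = np.asarray(x, dtype=float).ravel()
    m = x.size
    base = float(trained.predict(x[None, :])[0])
    perturbed = np.tile(x, (m, 1))
    perturbed[np.arange(m), np.arange(m)] += epsilon
    w = (trained.predict(perturbed) - base) / epsilon
    if np.all(w == 0.0):
        warnings.warn(
            f"all finite differences are zero at epsilon={epsilon:g}; if the "
            "model is not constant, increase epsilon", PrecisionWarning)
    return w


@dataclass
class CoefficientProfile:
    """Mean perturbation weights on an axis, optionally with per-spectrum rows."""

    axis: SpectralAxis
    mean_weights: np.ndarray
    per_spectrum_weights: np.ndarray | None = None
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        self.mean_weights = np.asarray(self.mean_weights, dtype=float)
        if self.mean_weights.size != len(self.axis):
            raise DomainError("mean_weights length must match the axis")
        if self.per_spectrum_weights is not None:
            W = np.asarray(self.per_spectrum_weights, dtype=float)
            if W.shape[1] != len(self.axis):
                raise DomainError("per-spectrum weight width must match the axis")
            self.per_spectrum_weights = W

    def to_frame(self, selected=None) -> pd.DataFrame:
        """Coefficient table with both axis units (and a selection flag)."""
        df = pd.DataFrame({
            "axis_cm-1": self.axis.in_unit(INV_CM),
            "axis_nm": self.axis.in_unit(NM),
            "mean_weight": self.mean_weights,
        })
        if selected is not None:
            flags = np.zeros(len(self.axis), dtype=bool)
            flags[np.asarray(selected, dtype=int)] = True
            df["selected"] = flags
        return df


def mean_coefficients(trained, X_train, epsilon: float = DEFAULT_EPSILON,
                      axis: SpectralAxis | None = None,
                      keep_per_spectrum: bool = False) -> CoefficientProfile:
    """Element-wise mean of per-spectrum weights over all training spectra."""
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise DomainError("X_train must be a non-empty n x m matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PrecisionWarning)
        W = np.vstack([per_spectrum_weights(trained, row, epsilon) for row in X])
    if np.all(W == 0.0):
        warnings.warn(
            f"all finite differences are zero at epsilon={epsilon:g}; if the "
            "model is not constant, increase epsilon", PrecisionWarning)
    if axis is None:
        axis = SpectralAxis(unit=NM, values=np.arange(1.0, X.shape[1] + 1.0))
    return CoefficientProfile(axis=axis, mean_weights=W.mean(axis=0),
                              per_spectrum_weights=W if keep_per_spectrum else None,
                              epsilon=epsilon)


@dataclass
class ImportantFeatures:
    """Indices beyond the signed cutoffs, with merged contiguous ranges."""

    threshold_fraction: float
    positive_cutoff: float
    negative_cutoff: float
    indices: np.ndarray
    ranges: list

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)


def _format_range(axis: SpectralAxis, i0: int, i1: int) -> str:
    """Human-readable interval in both units, wavenumbers descending."""
    cm = axis.in_unit(INV_CM)
    nm = axis.in_unit(NM)
    cm_pair = sorted((cm[i0], cm[i1]), reverse=True)
    nm_pair = sorted((nm[i0], nm[i1]))
    if i0 == i1:
        return f"{cm_pair[0]:.0f} cm-1 ({nm_pair[0]:.0f} nm)"
    return (f"{cm_pair[0]:.0f}-{cm_pair[1]:.0f} cm-1 "
            f"({nm_pair[0]:.0f}-{nm_pair[1]:.0f} nm)")


def select_important(profile: CoefficientProfile,
                     threshold_fraction: float = 0.50) -> ImportantFeatures:
    """Apply the signed threshold rule to a coefficient profile.

    positive_cutoff = fraction * max(w_bar), negative_cutoff = fraction *
    min(w_bar); a feature is selected when its mean weight is >= the positive
    cutoff or <= the negative cutoff. Raising the fraction never adds
    features.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise DomainError("threshold_fraction must be in (0, 1]")
    w = profile.mean_weights
    if np.ptp(w) < 1e-300:
        raise DegenerateInputError("all mean weights are equal: no peaks to threshold")
    pos_cut = threshold_fraction * w.max()
    neg_cut = threshold_fraction * w.min()
    mask = np.zeros(w.size, dtype=bool)
    if w.max() > 0:
        mask |= w >= pos_cut
    if w.min() < 0:
        mask |= w <= neg_cut
    idx = np.flatnonzero(mask)
    ranges = []
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(starts, ends):
            i0, i1 = int(idx[s]), int(idx[e])
            ranges.append({"start": i0, "stop": i1,
                           "label": _format_range(profile.axis, i0, i1)})
    return ImportantFeatures(threshold_fraction=threshold_fraction,
                             positive_cutoff=float(pos_cut),
                             negative_cutoff=float(neg_cut),
                             indices=idx, ranges=ranges)


def important_features_frame(features: ImportantFeatures) -> pd.DataFrame:
    """Merged-range report table."""
    return pd.DataFrame.from_records(
        [{"start_index": r["start"], "stop_index": r["stop"], "range": r["label"]}
         for r in features.ranges])
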