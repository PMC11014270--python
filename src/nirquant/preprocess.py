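"""Standard normal variate (SNV) preprocessing.

SNV standardizes each spectrum to zero mean and unit standard deviation
(sample, n-1 convention). Because it is per-row and fit-free it removes
per-spectrum multiplicative gain and additive baseline offset — exactly the
scatter effects a reflectance measurement adds — and can be applied before
train/test splitting without leakage.
"""

from __future__ import annotations

import numpy as np

from .dataset import SpectralDataset
from .errors import DegenerateInputError, DomainError

_SD_FLOOR = 1e-12


def snv(spectrum) -> np.ndarray:
    """(x - mean(x)) / sd(x) with sample (n-1) SD.

    Raises
    ------
    DegenerateInputError
        For a constant spectrum (SD below 1e-12), which SNV cannot scale.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DomainError("snv needs a 1-D spectrum of length >= 2")
    sd = x.std(ddof=1)
    if sd < _SD_FLOOR:
        raise DegenerateInputError("constant spectrum: SNV is undefined")
    return (x - x.mean()) / sd


def snv_matrix(X) -> np.ndarray:
    """Row-wise SNV of an n x m matrix (vectorized)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DomainError("snv_matrix needs an n x m matrix with m >= 2")
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.where(sd[:, 0] < _SD_FLOOR)[0]
    if bad.size:
        raise DegenerateInputError(f"constant spectrum at row {bad[0]}: SNV is undefined")
    return (X - X.mean(axis=1, keepdims=True)) / sd


def snv_dataset(dataset: SpectralDataset) -> SpectralDataset:
    """Row-wise SNV of a dataset; targets and metadata unchanged."""
    out = dataset.replace_X(snv_matrix(dataset.X), snv_applied=True)
    return out
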