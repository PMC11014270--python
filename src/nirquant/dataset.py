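"""Spectral dataset container, summary statistics, splitting and CSV I/O.

A dataset is an n x m absorbance matrix (log 1/R) on a shared axis, one
percent-adulteration target per spectrum, plus provenance metadata. The
on-disk form is a wide CSV (``sample_id,scan,level_percent,<axis values>``)
with a JSON metadata sidecar (``<stem>.meta.json``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .axes import INSTRUMENT_GRIDS, SpectralAxis, build_instrument_grid
from .errors import DomainError, SpectralFormatError

ADULTERANTS = ("corn_flour", "tapioca_starch")


@dataclass
class SpectrumRecord:
    """One scan of one physical sample."""

    sample_id: str
    level_percent: float
    scan_index: int
    absorbance: np.ndarray

    def __post_init__(self):
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if not np.isfinite(self.level_percent) or self.level_percent < 0:
            raise DomainError(
                f"level_percent must be finite and non-negative, got {self.level_percent}"
            )


@dataclass
class SpectralDataset:
    """Ordered spectra on one axis with targets and provenance metadata."""

    axis: SpectralAxis
    records: list[SpectrumRecord]
    metadata: dict = field(default_factory=dict)
    snv_applied: bool = False

    def __post_init__(self):
        m = len(self.axis)
        for i, rec in enumerate(self.records):
            if rec.absorbance.size != m:
                raise DomainError(
                    f"record {i} ({rec.sample_id!r}) has {rec.absorbance.size} "
                    f"absorbance values but the axis has {m} points"
                )

    # -- matrix views ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def m(self) -> int:
        return len(self.axis)

    @property
    def X(self) -> np.ndarray:
        """Row-major n x m absorbance matrix."""
        return np.vstack([r.absorbance for r in self.records]) if self.records \
            else np.empty((0, self.m))

    @property
    def y(self) -> np.ndarray:
        """Percent-adulteration target per spectrum."""
        return np.array([r.level_percent for r in self.records], dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def scans(self) -> np.ndarray:
        return np.array([r.scan_index for r in self.records], dtype=int)

    @classmethod
    def from_arrays(cls, axis: SpectralAxis, X, y, sample_ids=None, scans=None,
                    metadata: dict | None = None, snv_applied: bool = False
                    ) -> "SpectralDataset":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise DomainError(f"X shape {X.shape} incompatible with {y.size} targets")
        n = X.shape[0]
        sample_ids = sample_ids if sample_ids is not None else [f"s{i:04d}" for i in range(n)]
        scans = scans if scans is not None else np.ones(n, dtype=int)
        recs = [SpectrumRecord(str(sid), float(t), int(sc), row)
                for sid, t, sc, row in zip(sample_ids, y, scans, X)]
        return cls(axis=axis, records=recs, metadata=dict(metadata or {}),
                   snv_applied=snv_applied)

    def replace_X(self, X, snv_applied: bool | None = None) -> "SpectralDataset":
        """New dataset with the same bookkeeping but different absorbance rows."""
        out = SpectralDataset.from_arrays(
            self.axis, X, self.y, self.sample_ids, self.scans,
            metadata=dict(self.metadata),
            snv_applied=self.snv_applied if snv_applied is None else snv_applied)
        return out


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test row indices from one random permutation."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_fraction: float = 0.70
    seed: int = 42

    def __post_init__(self):
        tr = np.asarray(self.train_idx, dtype=int)
        te = np.asarray(self.test_idx, dtype=int)
        object.__setattr__(self, "train_idx", tr)
        object.__setattr__(self, "test_idx", te)
        if np.intersect1d(tr, te).size:
            raise DomainError("train and test indices overlap")


def split_train_test(dataset_or_n, train_fraction: float = 0.70, seed: int = 42
                     ) -> SplitIndices:
    """Uniform random 70/30-style split; |train| = floor(fraction * n).

    Deterministic for fixed (n, fraction, seed). For the study's n=450 at the
    default fraction this gives the 315:135 partition.
    """
    n = dataset_or_n.n if isinstance(dataset_or_n, SpectralDataset) else int(dataset_or_n)
    if not 0.0 < train_fraction < 1.0:
        raise DomainError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if n < 2:
        raise DomainError("need at least two rows to split")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(train_fraction * n))
    return SplitIndices(train_idx=np.sort(perm[:n_train]),
                        test_idx=np.sort(perm[n_train:]),
                        train_fraction=train_fraction, seed=seed)


def summarize(dataset: SpectralDataset, indices=None) -> dict:
    """Target summary over a row selection: n, m, min, max, mean, sd.

    SD uses the sample (n-1) convention; a single row reports sd = 0.
    """
    y = dataset.y
    if indices is not None:
        y = y[np.asarray(indices, dtype=int)]
    if y.size == 0:
        raise DomainError("empty selection")
    sd = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
    return {"n": int(y.size), "m": dataset.m, "min": float(y.min()),
            "max": float(y.max()), "mean": float(y.mean()), "sd": sd}


# ---------------------------------------------------------------------------
# CSV + JSON sidecar I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json") if p.suffix != ".csv" \
        else p.with_suffix(".meta.json")


def write_dataset_csv(dataset: SpectralDataset, path) -> Path:
    """Write the wide CSV and its JSON sidecar; returns the sidecar path."""
    path = Path(path)
    cols = [f"{v:.4f}" for v in dataset.axis.values]
    df = pd.DataFrame(dataset.X, columns=cols)
    df.insert(0, "level_percent", dataset.y)
    df.insert(0, "scan", dataset.scans)
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(path, index=False, float_format="%.12g")
    side = _sidecar_path(path)
    meta = {
        "unit": dataset.axis.unit,
        "instrument": dataset.axis.instrument_tag,
        "snv_applied": bool(dataset.snv_applied),
        **dataset.metadata,
    }
    side.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return side


def read_dataset_csv(path) -> SpectralDataset:
    """Read a wide CSV + sidecar back into a dataset, validating the contract."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise SpectralFormatError(f"metadata sidecar {side} not found")
    meta = json.loads(side.read_text())
    unit = meta.pop("unit", None)
    instrument = meta.get("instrument", "custom")
    snv_applied = bool(meta.pop("snv_applied", False))

    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SpectralFormatError(f"{path}: ragged or malformed CSV ({exc})") from exc
    required = ["sample_id", "scan", "level_percent"]
    if list(df.columns[:3]) != required:
        raise SpectralFormatError(
            f"{path}: header must start with {required}, got {list(df.columns[:3])}")
    axis_cols = list(df.columns[3:])
    if not axis_cols:
        raise SpectralFormatError(f"{path}: no spectral columns after metadata columns")
    try:
        axis_vals = np.array([float(c) for c in axis_cols])
    except ValueError as exc:
        raise SpectralFormatError(f"{path}: non-numeric axis header column ({exc})") from exc

    spec = df[axis_cols].apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(spec.to_numpy()))
    if bad.size:
        r, c = bad[0]
        raise SpectralFormatError(
            f"{path}: non-numeric or missing absorbance at row {r + 1}, "
            f"column {axis_cols[c]!r}")

    if instrument in INSTRUMENT_GRIDS:
        grid = build_instrument_grid(instrument)
        if unit != grid.unit:
            raise SpectralFormatError(
                f"{path}: sidecar unit {unit!r} does not match the {instrument} "
                f"canonical unit {grid.unit!r}")
        if axis_vals.size != len(grid) or not np.allclose(axis_vals, grid.values, atol=0.05):
            raise SpectralFormatError(
                f"{path}: axis columns do not match the canonical {instrument} grid "
                f"({axis_vals.size} vs {len(grid)} points)")
        axis = grid
    else:
        axis = SpectralAxis(unit=unit, values=axis_vals, instrument_tag=instrument)

    return SpectralDataset.from_arrays(
        axis, spec.to_numpy(dtype=float), df["level_percent"].to_numpy(dtype=float),
        sample_ids=df["sample_id"].astype(str).tolist(),
        scans=df["scan"].to_numpy(dtype=int),
        metadata=meta, snv_applied=snv_applied)
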