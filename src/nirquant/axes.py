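"""Spectral axis model: wavelength/wavenumber units and instrument grids.

NIR practice reports band positions in both wavelength (nm) and wavenumber
(cm^-1); the two are related by nu[cm^-1] * lambda[nm] = 10^7. Axes are stored
ascending in their native unit. Two canonical grids are built in:

* ``FT-NIR`` — benchtop Fourier-transform instrument, 1102 evenly spaced
  wavenumbers over 4000-12,500 cm^-1 (spacing ~7.72 cm^-1).
* ``Micro-NIR`` — portable instrument, 125 evenly spaced wavelengths over
  908-1676 nm (spacing ~6.19 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError

NM = "nm"
INV_CM = "cm-1"
UNITS = (NM, INV_CM)

FT_NIR = "FT-NIR"
MICRO_NIR = "Micro-NIR"

#: (unit, low, high, n_points) of the built-in instrument grids
INSTRUMENT_GRIDS = {
    FT_NIR: (INV_CM, 4000.0, 12500.0, 1102),
    MICRO_NIR: (NM, 908.0, 1676.0, 125),
}


def convert_axis(value, from_unit: str, to_unit: str):
    """Convert between wavelength (nm) and wavenumber (cm^-1).

    The map is ``x -> 10^7 / x`` when the units differ and the identity when
    they agree; it is an involution. Scalars and arrays are both accepted.

    Raises
    ------
    DomainError
        If ``value`` is not strictly positive (the conversion is a reciprocal).
    ConfigurationError
        If either unit is not ``"nm"`` or ``"cm-1"``.
    """
    for u in (from_unit, to_unit):
        if u not in UNITS:
            raise ConfigurationError(f"unknown axis unit {u!r}; expected one of {UNITS}")
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise DomainError("axis values must be finite and strictly positive")
    if from_unit == to_unit:
        return value if np.isscalar(value) else arr
    out = 1e7 / arr
    return float(out) if np.isscalar(value) else out


@dataclass(frozen=True)
class SpectralAxis:
    """A strictly ascending grid of spectral positions in one unit."""

    unit: str
    values: np.ndarray
    instrument_tag: str = "custom"

    def __post_init__(self):
        if self.unit not in UNITS:
            raise ConfigurationError(f"unknown axis unit {self.unit!r}")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise DomainError("axis needs at least two points")
        if not np.all(np.diff(vals) > 0):
            raise DomainError("axis values must be strictly ascending")
        if np.any(vals <= 0):
            raise DomainError("axis values must be positive")

    def __len__(self) -> int:
        return self.values.size

    def in_unit(self, unit: str) -> np.ndarray:
        """Per-point labels in ``unit`` (same ordering as the native axis)."""
        return np.asarray(convert_axis(self.values, self.unit, unit))

    def nearest_index(self, value: float, unit: str | None = None) -> int:
        """Grid index closest to ``value`` (given in ``unit``, default native)."""
        v = convert_axis(value, unit or self.unit, self.unit)
        return int(np.argmin(np.abs(self.values - v)))

    def to_dict(self) -> dict:
        return {"unit": self.unit, "instrument_tag": self.instrument_tag,
                "values": self.values.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralAxis":
        return cls(unit=d["unit"], values=np.asarray(d["values"], dtype=float),
                   instrument_tag=d.get("instrument_tag", "custom"))


def build_instrument_grid(instrument: str) -> SpectralAxis:
    """Canonical axis for a built-in instrument (``FT-NIR`` or ``Micro-NIR``)."""
    try:
        unit, lo, hi, n = INSTRUMENT_GRIDS[instrument]
    except KeyError:
        raise ConfigurationError(
            f"unknown instrument {instrument!r}; expected one of {sorted(INSTRUMENT_GRIDS)}"
        ) from None
    return SpectralAxis(unit=unit, values=np.linspace(lo, hi, n), instrument_tag=instrument)
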