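"""Synthetic mixture NIR spectra with the study's sampling design.

Pure components (coconut milk, corn flour, tapioca starch) are modelled as
sums of Gaussian absorption bands at the overtone/combination positions the
NIR literature assigns to water, fat CH and starch OH/glucose vibrations.
A mixture at adulterant mass fraction ``c`` has noise-free absorbance

    A(lam) = (1 - c) * A_milk(lam) * (1 - gamma * c) + c * A_adulterant(lam)

where ``gamma`` is a moisture-equilibration attenuation: a solid adulterant
binds free water, so milk-band peak absorbance drops faster than the linear
dilution alone — peaks decrease monotonically with adulteration level.
Measured spectra add per-sample multiplicative gain and baseline offset
(shared by a sample's replicate scans; removed by SNV) plus per-scan noise.

The default design mirrors a two-instrument adulteration study: 15 levels
(1-10, 15, 20, 30, 40, 50 % w/w) x 10 samples/level x 3 scans/sample = 450
spectra per instrument-adulterant pair, 1800 in total.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .axes import FT_NIR, MICRO_NIR, SpectralAxis, build_instrument_grid, convert_axis
from .dataset import ADULTERANTS, SpectralDataset, SpectrumRecord
from .errors import ConfigurationError, DomainError

DEFAULT_LEVELS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 30, 40, 50)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center/width in ``unit``, peak amplitude."""

    center: float
    width: float
    amplitude: float
    unit: str = "nm"
    label: str = ""

    def __post_init__(self):
        if self.width <= 0:
            raise DomainError("band width must be positive")
        if self.amplitude < 0:
            raise DomainError("band amplitude must be non-negative")


@dataclass(frozen=True)
class ComponentLibrary:
    """Band lists per component; serializable to/from plain config dicts."""

    components: dict

    def __post_init__(self):
        for name, bands in self.components.items():
            if len(bands) < 3:
                raise ConfigurationError(f"component {name!r} needs >= 3 bands")

    def bands(self, name: str) -> list[BandSpec]:
        try:
            return self.components[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown component {name!r}; have {sorted(self.components)}") from None

    def to_dict(self) -> dict:
        return {name: [{"center": b.center, "width": b.width, "amplitude": b.amplitude,
                        "unit": b.unit, "label": b.label} for b in bands]
                for name, bands in self.components.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ComponentLibrary":
        return cls({name: [BandSpec(**b) for b in bands] for name, bands in d.items()})


def default_library() -> ComponentLibrary:
    """Band library with centers at the standard NIR assignments.

    Centers follow the usual water (1452/1932 nm OH), fat CH (1210, 1728,
    1764 nm) and starch (1400 nm glucose region, 1540 nm OH, ~1930/2100 nm
    combination) positions. Widths and amplitudes are simulator defaults, not
    measured values.
    """
    nm = "nm"
    return ComponentLibrary({
        "coconut_milk": [
            BandSpec(1932.0, 45.0, 1.00, nm, "water OH combination"),
            BandSpec(1452.0, 35.0, 0.70, nm, "water OH first overtone"),
            BandSpec(1210.0, 25.0, 0.25, nm, "fat CH second overtone"),
            BandSpec(1728.0, 18.0, 0.20, nm, "fat CH first overtone"),
            BandSpec(1764.0, 18.0, 0.18, nm, "fat CH first overtone"),
            BandSpec(970.0, 30.0, 0.12, nm, "water OH second overtone"),
        ],
        "corn_flour": [
            BandSpec(1930.0, 50.0, 0.55, nm, "starch OH combination"),
            BandSpec(1540.0, 40.0, 0.50, nm, "starch OH first overtone"),
            BandSpec(1400.0, 35.0, 0.40, nm, "glucose OH region"),
            BandSpec(2100.0, 45.0, 0.35, nm, "starch O-H/C-O combination"),
            BandSpec(1210.0, 25.0, 0.22, nm, "CH second overtone"),
            BandSpec(1386.0, 15.0, 0.18, nm, "CH combination"),
        ],
        "tapioca_starch": [
            BandSpec(1930.0, 50.0, 0.52, nm, "starch OH combination"),
            BandSpec(1540.0, 38.0, 0.48, nm, "starch OH first overtone"),
            BandSpec(1400.0, 30.0, 0.45, nm, "glucose OH region"),
            BandSpec(2080.0, 45.0, 0.30, nm, "starch combination"),
            BandSpec(1212.0, 25.0, 0.20, nm, "CH second overtone"),
            BandSpec(1450.0, 30.0, 0.25, nm, "starch OH shoulder"),
        ],
    })


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-effect parameters.

    additive_sd           per-point white noise SD (absorbance), per scan
    multiplicative_range  per-sample gain g ~ U(lo, hi), shared across scans
    baseline_offset_range per-sample offset b0 ~ U(lo, hi), shared across scans
    moisture_attenuation  gamma in [0, 1): milk-band attenuation per unit c
    scan_noise_sd         per-scan scalar baseline jitter SD (absorbance)
    """

    additive_sd: float = 0.003
    multiplicative_range: tuple = (0.9, 1.1)
    baseline_offset_range: tuple = (-0.02, 0.02)
    moisture_attenuation: float = 0.3
    scan_noise_sd: float = 0.001

    def __post_init__(self):
        if self.additive_sd < 0 or self.scan_noise_sd < 0:
            raise DomainError("noise SDs must be non-negative")
        if not 0 <= self.moisture_attenuation < 1:
            raise DomainError("moisture_attenuation must be in [0, 1)")
        for name in ("multiplicative_range", "baseline_offset_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise DomainError(f"{name} must be ordered (lo <= hi)")

    @classmethod
    def off(cls) -> "NoiseModel":
        """Noise-free variant (deterministic expectation; gamma kept)."""
        return cls(additive_sd=0.0, multiplicative_range=(1.0, 1.0),
                   baseline_offset_range=(0.0, 0.0), scan_noise_sd=0.0)

    def to_dict(self) -> dict:
        return {"additive_sd": self.additive_sd,
                "multiplicative_range": list(self.multiplicative_range),
                "baseline_offset_range": list(self.baseline_offset_range),
                "moisture_attenuation": self.moisture_attenuation,
                "scan_noise_sd": self.scan_noise_sd}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        d = dict(d)
        for k in ("multiplicative_range", "baseline_offset_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design: levels x samples/level x scans/sample on one pair."""

    levels: tuple = DEFAULT_LEVELS
    samples_per_level: int = 10
    scans_per_sample: int = 3
    instrument: str = MICRO_NIR
    adulterant: str = "corn_flour"
    seed: int = 42

    def __post_init__(self):
        if self.samples_per_level < 1 or self.scans_per_sample < 1:
            raise DomainError("samples_per_level and scans_per_sample must be >= 1")
        if self.adulterant not in ADULTERANTS:
            raise ConfigurationError(
                f"unknown adulterant {self.adulterant!r}; expected one of {ADULTERANTS}")

    @property
    def n_spectra(self) -> int:
        return len(self.levels) * self.samples_per_level * self.scans_per_sample

    def to_dict(self) -> dict:
        return {"levels": list(self.levels), "samples_per_level": self.samples_per_level,
                "scans_per_sample": self.scans_per_sample, "instrument": self.instrument,
                "adulterant": self.adulterant, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        d = dict(d)
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Spectrum synthesis
# ---------------------------------------------------------------------------

def component_spectrum(bands, axis: SpectralAxis) -> np.ndarray:
    """Pointwise sum of Gaussian bands evaluated on the axis (non-negative).

    Each band is Gaussian in its own unit; the axis is converted to that unit
    before evaluation, so a band defined in nm renders correctly on a cm^-1
    grid and vice versa.
    """
    bands = list(bands)
    if not bands:
        raise DomainError("empty band list")
    out = np.zeros(len(axis))
    for b in bands:
        x = axis.in_unit(b.unit)
        out += b.amplitude * np.exp(-0.5 * ((x - b.center) / b.width) ** 2)
    return out


def expected_mixture(c: float, library: ComponentLibrary, axis: SpectralAxis,
                     adulterant: str = "corn_flour",
                     gamma: float = 0.3) -> np.ndarray:
    """Noise-free mixture absorbance at adulterant mass fraction ``c``.

    Affine in ``c`` when gamma = 0 and quadratic when gamma > 0; equals the
    pure milk spectrum at c = 0 and the pure adulterant spectrum at c = 1.
    """
    if not 0.0 <= c <= 1.0:
        raise DomainError(f"mass fraction c must be in [0, 1], got {c}")
    a_milk = component_spectrum(library.bands("coconut_milk"), axis)
    a_adu = component_spectrum(library.bands(adulterant), axis)
    return (1.0 - c) * a_milk * (1.0 - gamma * c) + c * a_adu


def simulate_mixture(c: float, library: ComponentLibrary, noise: NoiseModel | None,
                     axis: SpectralAxis, rng: np.random.Generator,
                     adulterant: str = "corn_flour") -> np.ndarray:
    """One noisy scan: gain/offset drawn per call, then per-scan noise."""
    noise = noise or NoiseModel.off()
    base = expected_mixture(c, library, axis, adulterant, noise.moisture_attenuation)
    g = rng.uniform(*noise.multiplicative_range)
    b0 = rng.uniform(*noise.baseline_offset_range)
    return _apply_scan_noise(g * base + b0, noise, rng)


def _apply_scan_noise(spec: np.ndarray, noise: NoiseModel,
                      rng: np.random.Generator) -> np.ndarray:
    out = spec.copy()
    if noise.scan_noise_sd > 0:
        out += rng.normal(0.0, noise.scan_noise_sd)
    if noise.additive_sd > 0:
        out += rng.normal(0.0, noise.additive_sd, size=out.shape)
    return out


def generate_design(spec: DesignSpec, library: ComponentLibrary | None = None,
                    noise: NoiseModel | None = None) -> SpectralDataset:
    """Full dataset for one instrument-adulterant pair.

    Per-sample gain/offset are shared across that sample's scans; scan-level
    noise is independent. Fully deterministic given ``spec.seed``.
    """
    library = library or default_library()
    noise = noise or NoiseModel()
    axis = build_instrument_grid(spec.instrument)
    rng = np.random.default_rng(spec.seed)
    records = []
    for level in spec.levels:
        base = expected_mixture(level / 100.0, library, axis, spec.adulterant,
                                noise.moisture_attenuation)
        for s in range(spec.samples_per_level):
            g = rng.uniform(*noise.multiplicative_range)
            b0 = rng.uniform(*noise.baseline_offset_range)
            sample = g * base + b0
            sid = f"{spec.adulterant[:4]}-L{level:g}-{s:02d}"
            for scan in range(1, spec.scans_per_sample + 1):
                records.append(SpectrumRecord(
                    sample_id=sid, level_percent=float(level), scan_index=scan,
                    absorbance=_apply_scan_noise(sample, noise, rng)))
    meta = {"instrument": spec.instrument, "adulterant": spec.adulterant,
            "generator_seed": int(spec.seed), "design": spec.to_dict(),
            "noise": noise.to_dict()}
    return SpectralDataset(axis=axis, records=records, metadata=meta)


def derive_seed(master_seed: int, *tags: str) -> int:
    """Stable per-stream sub-seed (< 2^31) from a master seed and string tags."""
    key = zlib.crc32("|".join(tags).encode())
    return int(np.random.SeedSequence([int(master_seed), key]).generate_state(1)[0] % (2 ** 31))


def generate_full_study(seed: int = 42, library: ComponentLibrary | None = None,
                        noise: NoiseModel | None = None,
                        design: DesignSpec | None = None) -> dict:
    """All four datasets (2 instruments x 2 adulterants), 1800 spectra total.

    Per-dataset seeds are derived from the master seed and the pair's tags so
    each dataset is independently reproducible.
    """
    base = design or DesignSpec()
    out = {}
    for instrument in (FT_NIR, MICRO_NIR):
        for adulterant in ADULTERANTS:
            spec = replace(base, instrument=instrument, adulterant=adulterant,
                           seed=derive_seed(seed, instrument, adulterant))
            out[(instrument, adulterant)] = generate_design(spec, library, noise)
    return out
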