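"""Synthetic NIR diffuse-reflectance datasets with known ground truth.

Real NIR spectra of the herbal matrix are not deposited anywhere, so
end-to-end tests run on simulated data that reproduces the statistical
structure a PLS calibration assumes: Beer-Lambert linear mixing of a
band-structured analyte spectrum with broad interfering matrix
components, per-sample multiplicative/additive scatter, slow baseline
drift, and heteroscedastic detector noise that is an order of
magnitude worse at the low-wavenumber end of the range (where fibre
absorption saturates real instruments). The generator makes no claim
of spectroscopic fidelity for the analyte beyond its known band
positions; it provides ground truth, not physics.

Analyte band centres follow the assignments typical of a cycloartane
glycoside: C-H combination bands at 4250/4357 cm^-1, C-C/C=C at
4762 cm^-1, the acetyl C=O second overtone near 5168 cm^-1, the C-H
first overtone at 5776 cm^-1, O-H first overtone at 6848 cm^-1 and
the C-H second overtone near 8248 cm^-1.

All randomness derives from a single seed through per-sample
substreams (``default_rng([seed, index])``), so generating more
samples never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hplc_elsd import table2_fixture
from .spectra_io import Dataset, SampleRecord, SpectrumSet, WavenumberAxis

__all__ = [
    "BandSpec",
    "ComponentSpectrum",
    "GeneratorConfig",
    "make_component",
    "generate",
    "table2_contents",
    "default_analyte",
    "default_interferents",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band."""

    center: float     # cm^-1
    width: float      # Gaussian sigma, cm^-1
    amplitude: float  # absorbance per unit concentration

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("band amplitude must be finite")


@dataclass(frozen=True)
class ComponentSpectrum:
    """A named pure-component spectrum as a sum of Gaussian bands."""

    name: str
    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError(f"component {self.name!r} needs at least one band")


# Width defaults: ~60 cm^-1 sigma in the combination region (< 6500
# cm^-1), ~120 cm^-1 for the broader overtone bands above it.
_COMBINATION_WIDTH = 60.0
_OVERTONE_WIDTH = 120.0

_ANALYTE_CENTERS = (4250.0, 4357.0, 4762.0, 5168.0, 5776.0, 6848.0, 8248.0)
# Relative band strengths; the whole component is rescaled so that a
# 0.3 % w/w content contributes ~0.05 absorbance at the 5168 cm^-1 band.
_ANALYTE_RELATIVE = (0.8, 0.7, 0.6, 1.0, 0.9, 0.5, 0.25)
_ANALYTE_TARGET_ABS = 0.05
_ANALYTE_TARGET_CONTENT = 0.3


def default_analyte() -> ComponentSpectrum:
    """Band-structured analyte spectrum on the default amplitude scale."""
    bands = [
        BandSpec(
            c,
            _COMBINATION_WIDTH if c < 6500 else _OVERTONE_WIDTH,
            rel,
        )
        for c, rel in zip(_ANALYTE_CENTERS, _ANALYTE_RELATIVE)
    ]
    # scale so content * analyte hits the target absorbance at 5168
    probe = sum(
        b.amplitude * np.exp(-((5168.0 - b.center) ** 2) / (2 * b.width**2))
        for b in bands
    )
    scale = _ANALYTE_TARGET_ABS / (_ANALYTE_TARGET_CONTENT * probe)
    return ComponentSpectrum(
        "analyte",
        tuple(BandSpec(b.center, b.width, b.amplitude * scale) for b in bands),
    )


def default_interferents() -> tuple[ComponentSpectrum, ...]:
    """Broad matrix components that overlap the analyte bands.

    Honey-sugar-like, cellulose-like and water-like components carry
    mass fractions near 1 and deliberately share the 5168 and 6848
    cm^-1 regions with the analyte, so that window and factor
    selection genuinely matter. Amplitudes put the total matrix
    absorbance near 1 AU in the combination region, typical of
    log(1/R) spectra of powdered plant material, which keeps the
    minor analyte a small fraction of the total signal.
    """
    return (
        ComponentSpectrum(
            "honey-sugar-like",
            (
                BandSpec(4400.0, 90.0, 0.54),
                BandSpec(4800.0, 110.0, 0.45),
                BandSpec(5168.0, 140.0, 0.36),
                BandSpec(5900.0, 130.0, 0.30),
                BandSpec(6848.0, 200.0, 0.24),
            ),
        ),
        ComponentSpectrum(
            "cellulose-like",
            (
                BandSpec(4280.0, 80.0, 0.66),
                BandSpec(4740.0, 100.0, 0.42),
                BandSpec(5600.0, 160.0, 0.30),
                BandSpec(6300.0, 180.0, 0.21),
                BandSpec(8300.0, 260.0, 0.12),
            ),
        ),
        ComponentSpectrum(
            "water-like",
            (
                BandSpec(5168.0, 180.0, 0.60),
                BandSpec(6900.0, 240.0, 0.36),
                BandSpec(8600.0, 300.0, 0.09),
            ),
        ),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full statistical specification of one synthetic dataset.

    Defaults give a 150-sample set on a 4000-10000 cm^-1 grid with
    4 cm^-1 spacing, contents taken from the embedded determination
    table (0.12-0.52 % w/w with one high outlier), 2% relative
    compositional variation of the matrix, 5% multiplicative and 0.01
    absorbance additive scatter, mild linear baseline drift, and
    1e-4 absorbance noise that is 10x worse below 4200 cm^-1.
    """

    seed: int
    n_samples: int = 150
    axis_low: float = 4000.0
    axis_high: float = 10000.0
    axis_step: float = 4.0
    analyte: ComponentSpectrum = field(default_factory=default_analyte)
    interferents: tuple[ComponentSpectrum, ...] = field(
        default_factory=default_interferents
    )
    content_source: str | Sequence[float] = "table2"  # or "uniform", or a list
    content_range: tuple[float, float] = (0.12, 0.52)  # for "uniform"
    interferent_concentration_sd: float = 0.02  # relative (lognormal)
    baseline_offset_sd: float = 0.02           # absorbance
    baseline_slope_sd: float = 2e-6            # absorbance per cm^-1
    scatter_multiplicative_sd: float = 0.05
    scatter_additive_sd: float = 0.01
    noise_sd: float = 1e-4                     # absorbance
    noisy_region: tuple[float, float] = (4000.0, 4200.0)
    noisy_region_factor: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "interferent_concentration_sd",
            "baseline_offset_sd",
            "baseline_slope_sd",
            "scatter_multiplicative_sd",
            "scatter_additive_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if isinstance(self.content_source, str) and self.content_source not in (
            "table2",
            "uniform",
        ):
            raise ValueError("content_source must be 'table2', 'uniform' or a list")

    def axis(self) -> WavenumberAxis:
        return WavenumberAxis.regular(self.axis_low, self.axis_high, self.axis_step)


def make_component(bands: Sequence[BandSpec], axis: WavenumberAxis) -> np.ndarray:
    """Evaluate a sum of Gaussian bands on the axis."""
    wn = axis.values
    out = np.zeros_like(wn)
    for b in bands:
        out += b.amplitude * np.exp(-((wn - b.center) ** 2) / (2 * b.width**2))
    return out


def table2_contents(n: int = 150) -> list[float]:
    """First n contents of the embedded determination table, in order."""
    fixture = table2_fixture()
    if n > len(fixture):
        raise ValueError(f"only {len(fixture)} fixture contents available")
    return [r.content for r in fixture[:n]]


def _content(config: GeneratorConfig, i: int, rng: np.random.Generator) -> float:
    src = config.content_source
    if isinstance(src, str):
        if src == "table2":
            return table2_contents(150)[i % 150]
        low, high = config.content_range
        return float(rng.uniform(low, high))
    return float(src[i])


def generate(config: GeneratorConfig) -> Dataset:
    """Generate a Dataset; records carry the true contents.

    Per sample: clean = y*analyte + sum_j c_j*interferent_j +
    (a + b*wavenumber); observed = m*clean + offset + noise, with
    m ~ N(1, scatter_multiplicative_sd), offset ~ N(0,
    scatter_additive_sd), c_j lognormal around 1 and noise
    heteroscedastic over the axis.
    """
    axis = config.axis()
    wn = axis.values
    analyte = make_component(config.analyte.bands, axis)
    interferents = np.array(
        [make_component(c.bands, axis) for c in config.interferents]
    )
    noise_scale = np.full(wn.size, float(config.noise_sd))
    lo, hi = config.noisy_region
    noise_scale[(wn >= lo) & (wn <= hi)] *= config.noisy_region_factor

    rows = np.empty((config.n_samples, wn.size))
    records = []
    sigma = config.interferent_concentration_sd
    for i in range(config.n_samples):
        rng = np.random.default_rng([config.seed, i])
        y = _content(config, i, rng)
        if y <= 0:
            raise ValueError(f"sample {i}: content must be positive")
        conc = np.exp(rng.normal(0.0, sigma, size=len(interferents))) if sigma else np.ones(len(interferents))
        clean = y * analyte + conc @ interferents
        clean += rng.normal(0.0, config.baseline_offset_sd) + rng.normal(
            0.0, config.baseline_slope_sd
        ) * (wn - wn[0])
        mult = rng.normal(1.0, config.scatter_multiplicative_sd)
        add = rng.normal(0.0, config.scatter_additive_sd)
        noise = rng.normal(0.0, 1.0, size=wn.size) * noise_scale
        rows[i] = mult * clean + add + noise
        records.append(SampleRecord(id=f"Syn {i + 1}", content=y))
    return Dataset(SpectrumSet(axis, rows, tuple(r.id for r in records)), records)
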