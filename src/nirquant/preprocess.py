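"""Spectral pretreatment operators and fitted pipelines.

Implements the pretreatments routinely screened when building NIR
calibrations: standard normal variate (SNV), multiplicative scatter
correction (MSC), finite-difference first/second derivatives (FD/SD),
Savitzky-Golay smoothing/differentiation (SG), and the Norris
gap-segment derivative. Pipelines compose steps in order; MSC is the
one stateful step (its reference spectrum is the mean calibration
spectrum and must never be re-fitted on prediction data).

Derivative-type operators require a uniform wavenumber grid. Spectra
that have been cut to multiple windows have spacing jumps at window
junctions; those operators are applied independently on each maximal
uniform segment, so no derivative ever spans a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.ndimage import uniform_filter1d

from .spectra_io import SpectrumSet, WavenumberAxis

__all__ = [
    "PreprocessStep",
    "PreprocessPipeline",
    "snv",
    "msc_fit",
    "msc_apply",
    "derivative_fd",
    "savgol",
    "norris",
    "fit_apply_pipeline",
    "pipeline_from_label",
    "PIPELINE_LABELS",
]

_KINDS = ("snv", "msc", "fd", "sd", "savgol", "norris", "identity")


@dataclass(frozen=True)
class PreprocessStep:
    """One named pretreatment with its parameters.

    kinds: snv | msc | fd (finite-difference, order param) | sd
    (finite-difference second derivative) | savgol (window, polyorder,
    deriv) | norris (segment, gap, order) | identity.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown step kind {self.kind!r}; valid: {_KINDS}")
        p = self.params
        if self.kind == "savgol":
            w, po = p.get("window", 11), p.get("polyorder", 3)
            if w % 2 == 0 or w <= po:
                raise ValueError("savgol window must be odd and > polyorder")
            if p.get("deriv", 0) not in (0, 1, 2):
                raise ValueError("savgol deriv must be 0, 1 or 2")
        if self.kind == "norris":
            if p.get("segment", 5) < 1 or p.get("gap", 5) < 1:
                raise ValueError("norris segment and gap must be >= 1")
            if p.get("order", 1) not in (1, 2):
                raise ValueError("norris order must be 1 or 2")
        if self.kind == "fd" and p.get("order", 1) not in (1, 2):
            raise ValueError("fd order must be 1 or 2")


def _uniform_segments(axis: WavenumberAxis, rtol: float = 1e-6) -> list[slice]:
    """Maximal contiguous runs with uniform spacing (window junctions break)."""
    wn = axis.values
    d = np.diff(wn)
    step = np.median(d)
    breaks = np.flatnonzero(np.abs(d - step) > rtol * step)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [wn.size]))
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


def _per_segment(spectra: SpectrumSet, func) -> SpectrumSet:
    out = np.empty_like(spectra.absorbance)
    for seg in _uniform_segments(spectra.axis):
        wn = spectra.axis.values[seg]
        if wn.size < 3:
            raise ValueError("uniform axis segment too short for differentiation")
        step = float(wn[1] - wn[0])
        out[:, seg] = func(spectra.absorbance[:, seg], step)
    return spectra.with_absorbance(out)


def snv(spectra: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: centre and scale each spectrum row-wise.

    Output rows have mean 0 and sample (n-1) standard deviation 1.
    """
    x = spectra.absorbance
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"constant spectrum, SNV undefined: {spectra.sample_ids[bad[0]]!r}")
    return spectra.with_absorbance((x - mu) / sd)


def msc_fit(spectra: SpectrumSet) -> np.ndarray:
    """MSC reference spectrum: column-wise mean of the calibration set."""
    if spectra.n_samples < 2:
        raise ValueError("MSC reference needs at least two calibration spectra")
    return spectra.absorbance.mean(axis=0)


def msc_apply(spectra: SpectrumSet, reference: np.ndarray) -> SpectrumSet:
    """Remove per-spectrum affine scatter distortion against a reference.

    Each row x is regressed x = a + b * reference by OLS over all
    points; the corrected row is (x - a) / b.
    """
    r = np.asarray(reference, dtype=float)
    if r.shape != (spectra.n_points,):
        raise ValueError("MSC reference is not on the spectra's axis")
    x = spectra.absorbance
    rc = r - r.mean()
    denom = float(rc @ rc)
    if denom == 0:
        raise ValueError("MSC reference is constant")
    b = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
    bad = np.flatnonzero(np.abs(b) < 1e-12)
    if bad.size:
        raise ValueError(
            f"MSC slope vanishes for sample {spectra.sample_ids[bad[0]]!r}"
        )
    a = x.mean(axis=1) - b * r.mean()
    return spectra.with_absorbance((x - a[:, None]) / b[:, None])


def _fd1(x: np.ndarray, step: float) -> np.ndarray:
    out = np.empty_like(x)
    out[:, 1:-1] = (x[:, 2:] - x[:, :-2]) / (2 * step)
    if x.shape[1] >= 3:  # second-order one-sided ends
        out[:, 0] = (-3 * x[:, 0] + 4 * x[:, 1] - x[:, 2]) / (2 * step)
        out[:, -1] = (3 * x[:, -1] - 4 * x[:, -2] + x[:, -3]) / (2 * step)
    return out


def _fd2(x: np.ndarray, step: float) -> np.ndarray:
    out = np.empty_like(x)
    out[:, 1:-1] = (x[:, 2:] - 2 * x[:, 1:-1] + x[:, :-2]) / step**2
    if x.shape[1] >= 4:
        out[:, 0] = (2 * x[:, 0] - 5 * x[:, 1] + 4 * x[:, 2] - x[:, 3]) / step**2
        out[:, -1] = (2 * x[:, -1] - 5 * x[:, -2] + 4 * x[:, -3] - x[:, -4]) / step**2
    else:
        out[:, 0] = out[:, -1] = out[:, 1]
    return out


def derivative_fd(spectra: SpectrumSet, order: int = 1) -> SpectrumSet:
    """Central finite-difference derivative scaled by the grid spacing.

    Interior points use the standard central stencils; endpoints use
    one-sided stencils of the same order of accuracy, so the output has
    the input's length.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    return _per_segment(spectra, _fd1 if order == 1 else _fd2)


def savgol(
    spectra: SpectrumSet, window: int = 11, polyorder: int = 3, deriv: int = 0
) -> SpectrumSet:
    """Savitzky-Golay smoothing / differentiation.

    Least-squares polynomial of degree `polyorder` over a moving window
    of `window` points; `deriv`-th derivative at the window centre,
    scaled by the grid spacing. Edge points are evaluated from a
    polynomial fitted to the terminal window.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if deriv > polyorder:
        raise ValueError("deriv must not exceed polyorder")

    def op(x: np.ndarray, step: float) -> np.ndarray:
        if window > x.shape[1]:
            raise ValueError(
                f"savgol window {window} exceeds segment length {x.shape[1]}"
            )
        return savgol_filter(
            x, window, polyorder, deriv=deriv, delta=step, axis=1, mode="interp"
        )

    return _per_segment(spectra, op)


def norris(
    spectra: SpectrumSet, segment: int = 5, gap: int = 5, order: int = 1
) -> SpectrumSet:
    """Norris gap-segment derivative.

    Each point is replaced by the difference of segment means taken
    `gap` points to either side: D1_i = (S_{i+g} - S_{i-g}) / (2 g dv),
    D2_i = (S_{i+g} - 2 S_i + S_{i-g}) / (g dv)^2, with S the moving
    mean over `segment` points. Points whose segments would fall off
    the axis copy the nearest valid value.
    """
    if segment < 1 or gap < 1:
        raise ValueError("segment and gap must be >= 1")
    if segment % 2 == 0:
        raise ValueError("segment must be odd (segments are centred)")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    half = (segment - 1) // 2

    def op(x: np.ndarray, step: float) -> np.ndarray:
        n = x.shape[1]
        if 2 * gap + segment >= n:
            raise ValueError(
                f"2*gap + segment = {2 * gap + segment} must be < segment length {n}"
            )
        s = uniform_filter1d(x, segment, axis=1, mode="nearest")
        lo, hi = gap + half, n - 1 - gap - half  # indices with fully valid segments
        out = np.empty_like(x)
        if order == 1:
            d = (s[:, 2 * gap :] - s[:, : n - 2 * gap]) / (2 * gap * step)
        else:
            d = (s[:, 2 * gap :] - 2 * s[:, gap : n - gap] + s[:, : n - 2 * gap]) / (
                gap * step
            ) ** 2
        # d[:, k] corresponds to centre index k + gap
        out[:, lo : hi + 1] = d[:, lo - gap : hi - gap + 1]
        out[:, :lo] = out[:, [lo]]
        out[:, hi + 1 :] = out[:, [hi]]
        return out

    return _per_segment(spectra, op)


@dataclass
class PreprocessPipeline:
    """An ordered list of steps with fitted MSC state.

    Fit on calibration spectra only; `transform` then applies the same
    frozen state to any spectra on the same axis.
    """

    steps: list[PreprocessStep]
    msc_references: dict[int, np.ndarray] = field(default_factory=dict)
    _fitted: bool = False

    def fit(self, calibration: SpectrumSet) -> "PreprocessPipeline":
        if calibration.n_samples == 0:
            raise ValueError("cannot fit a pipeline on an empty calibration set")
        current = calibration
        self.msc_references = {}
        for i, step in enumerate(self.steps):
            if step.kind == "msc":
                self.msc_references[i] = msc_fit(current)
            current = self._apply_step(i, step, current)
        self._fitted = True
        return self

    def transform(self, spectra: SpectrumSet) -> SpectrumSet:
        if not self._fitted:
            raise RuntimeError("pipeline must be fitted before transform")
        current = spectra
        for i, step in enumerate(self.steps):
            current = self._apply_step(i, step, current)
        return current

    def _apply_step(
        self, i: int, step: PreprocessStep, spectra: SpectrumSet
    ) -> SpectrumSet:
        p = step.params
        if step.kind == "identity":
            return spectra
        if step.kind == "snv":
            return snv(spectra)
        if step.kind == "msc":
            return msc_apply(spectra, self.msc_references[i])
        if step.kind == "fd":
            return derivative_fd(spectra, p.get("order", 1))
        if step.kind == "sd":
            return derivative_fd(spectra, 2)
        if step.kind == "savgol":
            return savgol(
                spectra,
                p.get("window", 11),
                p.get("polyorder", 3),
                p.get("deriv", 0),
            )
        if step.kind == "norris":
            return norris(
                spectra, p.get("segment", 5), p.get("gap", 5), p.get("order", 1)
            )
        raise AssertionError(step.kind)

    def spec(self) -> list[dict]:
        """JSON-serialisable description (without fitted state)."""
        return [{"kind": s.kind, "params": dict(s.params)} for s in self.steps]


def fit_apply_pipeline(
    steps: Sequence[PreprocessStep], calibration: SpectrumSet, target: SpectrumSet
) -> tuple[PreprocessPipeline, SpectrumSet]:
    """Fit stateful steps on `calibration`, apply all steps to `target`."""
    pipe = PreprocessPipeline(list(steps)).fit(calibration)
    return pipe, pipe.transform(target)


# Composite labels as they appear in pretreatment screening tables.
# "X + SG" couples the derivative into a single Savitzky-Golay
# differentiation step rather than differencing then smoothing.
def _label_steps() -> dict[str, list[PreprocessStep]]:
    sg = lambda d: PreprocessStep("savgol", {"window": 11, "polyorder": 3, "deriv": d})
    out: dict[str, list[PreprocessStep]] = {}
    for scatter in ("MSC", "SNV"):
        base = PreprocessStep(scatter.lower())
        out[f"{scatter} + Spectrum"] = [base]
        out[f"{scatter} + FD"] = [base, PreprocessStep("fd", {"order": 1})]
        out[f"{scatter} + SD"] = [base, PreprocessStep("fd", {"order": 2})]
        out[f"{scatter} + FD + SG"] = [base, sg(1)]
        out[f"{scatter} + SD + SG"] = [base, sg(2)]
    out["Spectrum"] = [PreprocessStep("identity")]
    out["FD"] = [PreprocessStep("fd", {"order": 1})]
    out["SD"] = [PreprocessStep("fd", {"order": 2})]
    out["FD + SG"] = [sg(1)]
    out["SD + SG"] = [sg(2)]
    out["SG"] = [sg(0)]
    out["Norris"] = [PreprocessStep("norris")]
    return out


PIPELINE_LABELS: dict[str, list[PreprocessStep]] = _label_steps()


def pipeline_from_label(label: str) -> list[PreprocessStep]:
    """Resolve a screening-table label like ``"MSC + SD + SG"`` to steps."""
    key = " + ".join(part.strip() for part in label.split("+"))
    if key not in PIPELINE_LABELS:
        raise ValueError(
            f"unknown pipeline label {label!r}; valid labels: {sorted(PIPELINE_LABELS)}"
        )
    return list(PIPELINE_LABELS[key])
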