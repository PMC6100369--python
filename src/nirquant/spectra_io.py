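"""Spectral data containers and CSV I/O.

The in-memory model is deliberately small: a :class:`WavenumberAxis`
(strictly ascending cm^-1 grid), a :class:`SpectrumSet` (samples x
wavenumbers absorbance matrix), per-sample metadata in
:class:`SampleRecord`, and the pairing of the two in :class:`Dataset`.
Spectra are exchanged as wide CSV files whose header is
``id,<metadata columns>,<wavenumber>,<wavenumber>,...``; instruments
commonly report the axis descending, so the reader canonicalises to
ascending order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberAxis",
    "SpectrumSet",
    "SampleRecord",
    "Dataset",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_metadata_csv",
    "subset_windows",
]

#: Plausible NIR wavenumber range (cm^-1) accepted by WavenumberAxis.
AXIS_MIN = 3800.0
AXIS_MAX = 12500.0

_METADATA_COLUMNS = ("origin", "content", "peak_area", "role")
_ROLES = ("pool", "calibration", "validation")


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis needs at least two wavenumber points")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if values[0] < AXIS_MIN or values[-1] > AXIS_MAX:
            raise ValueError(
                f"axis must lie within [{AXIS_MIN:g}, {AXIS_MAX:g}] cm^-1"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def step(self) -> float:
        """Nominal (median) spacing in cm^-1."""
        return float(np.median(np.diff(self.values)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.values)
        return bool(np.all(np.abs(d - d.mean()) <= rtol * abs(d.mean())))

    @classmethod
    def regular(cls, low: float, high: float, step: float) -> "WavenumberAxis":
        n = int(round((high - low) / step)) + 1
        return cls(low + step * np.arange(n))


@dataclass(frozen=True)
class SpectrumSet:
    """Absorbance matrix (n_samples x n_points) on a shared axis."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x points)")
        object.__setattr__(self, "absorbance", a)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if a.shape[1] != len(self.axis):
            raise ValueError(
                f"absorbance has {a.shape[1]} columns but axis has {len(self.axis)} points"
            )
        if a.shape[0] != len(self.sample_ids):
            raise ValueError("one sample id per spectrum required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectrumSet":
        """Same axis and ids, new matrix (used by axis-preserving operators)."""
        return SpectrumSet(self.axis, absorbance, self.sample_ids)

    def take(self, indices: Sequence[int]) -> "SpectrumSet":
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(
            self.axis,
            self.absorbance[idx],
            tuple(self.sample_ids[i] for i in idx),
        )


@dataclass
class SampleRecord:
    """Per-sample metadata: reference content (% w/w), ELSD peak area, role."""

    id: str
    origin: str | None = None
    content: float | None = None
    peak_area: float | None = None
    role: str = "pool"

    def __post_init__(self) -> None:
        if self.content is not None and not (0.0 < self.content < 100.0):
            raise ValueError(f"{self.id}: content must be in (0, 100) % w/w")
        if self.peak_area is not None and self.peak_area <= 0:
            raise ValueError(f"{self.id}: peak area must be positive")
        if self.role not in _ROLES:
            raise ValueError(f"{self.id}: role must be one of {_ROLES}")


@dataclass
class Dataset:
    """A SpectrumSet together with aligned sample records."""

    spectra: SpectrumSet
    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if [r.id for r in self.records] != list(self.spectra.sample_ids):
            raise ValueError("records must align 1:1 with spectra rows by id")

    @property
    def contents(self) -> np.ndarray:
        """Reference contents (% w/w); raises if any are missing."""
        y = [r.content for r in self.records]
        if any(v is None for v in y):
            missing = [r.id for r in self.records if r.content is None][:5]
            raise ValueError(f"missing reference content for samples {missing}")
        return np.asarray(y, dtype=float)

    def subset_role(self, role: str) -> "Dataset":
        idx = [i for i, r in enumerate(self.records) if r.role == role]
        return self.take(idx)

    def take(self, indices: Sequence[int]) -> "Dataset":
        return Dataset(
            self.spectra.take(indices),
            [replace(self.records[i]) for i in indices],
        )


def _split_columns(columns: Iterable[str]) -> tuple[list[str], list[str]]:
    meta, wn = [], []
    for c in columns:
        try:
            float(c)
        except ValueError:
            meta.append(c)
        else:
            wn.append(c)
    return meta, wn


def read_spectra_csv(path: str | Path) -> Dataset:
    """Read a wide spectral CSV into a Dataset.

    Wavenumber columns are recognised as numeric headers; any of
    ``origin, content, peak_area, role`` are mapped onto SampleRecord
    fields. A descending axis in the file is reversed to ascending.
    """
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing 'id' column")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    meta_cols, wn_cols = _split_columns(c for c in df.columns if c != "id")
    if len(wn_cols) < 2:
        raise ValueError(f"{path}: fewer than two wavenumber columns")
    wn = np.array([float(c) for c in wn_cols])
    order = np.argsort(wn)
    if np.unique(wn).size != wn.size:
        raise ValueError(f"{path}: duplicate wavenumber columns")
    axis = WavenumberAxis(wn[order])
    absorb = df[wn_cols].to_numpy(dtype=float)[:, order]
    if np.isnan(absorb).any():
        raise ValueError(f"{path}: missing absorbance values (ragged rows?)")
    spectra = SpectrumSet(axis, absorb, tuple(df["id"]))
    records = []
    for _, row in df.iterrows():
        kw: dict = {"id": str(row["id"])}
        for c in meta_cols:
            if c not in _METADATA_COLUMNS:
                continue
            v = row[c]
            if pd.isna(v):
                continue
            kw[c] = float(v) if c in ("content", "peak_area") else str(v)
        records.append(SampleRecord(**kw))
    return Dataset(spectra, records)


def write_spectra_csv(dataset: Dataset, path: str | Path) -> None:
    """Write the dialect read_spectra_csv accepts, at full float precision."""
    axis = dataset.spectra.axis
    cols: dict = {"id": list(dataset.spectra.sample_ids)}
    for name in _METADATA_COLUMNS:
        vals = [getattr(r, name) for r in dataset.records]
        if any(v is not None for v in vals):
            cols[name] = vals
    for j, wn in enumerate(axis.values):
        cols[repr(float(wn))] = dataset.spectra.absorbance[:, j]
    # shortest round-trippable decimal repr keeps files readable and exact
    pd.DataFrame(cols).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_metadata_csv(path: str | Path) -> list[SampleRecord]:
    """Read a metadata-only CSV (id, origin, content, peak_area, role)."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing 'id' column")
    records = []
    for _, row in df.iterrows():
        kw: dict = {"id": str(row["id"])}
        for c in _METADATA_COLUMNS:
            if c in df.columns and not pd.isna(row[c]):
                kw[c] = float(row[c]) if c in ("content", "peak_area") else str(row[c])
        records.append(SampleRecord(**kw))
    return records


def subset_windows(
    spectra: SpectrumSet, windows: Sequence[Sequence[float]]
) -> SpectrumSet:
    """Keep axis points inside at least one [low, high] window (inclusive).

    Overlapping windows deduplicate; ascending order is preserved.
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    wn = spectra.axis.values
    mask = np.zeros(wn.size, dtype=bool)
    for low, high in windows:
        if not low < high:
            raise ValueError(f"window [{low}, {high}] must have low < high")
        mask |= (wn >= low) & (wn <= high)
    if not mask.any():
        raise ValueError("windows select no axis points")
    return SpectrumSet(
        WavenumberAxis(wn[mask]), spectra.absorbance[:, mask], spectra.sample_ids
    )
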