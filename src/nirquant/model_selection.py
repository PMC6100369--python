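"""Calibration/validation handling, subset design, metrics and grids.

Covers the bookkeeping around a PLS calibration: seeded random
120/30-style splits, "boxcar" subset selection (picking a calibration
set whose reference contents are near-uniform over their range, the
stated goal of commercial sample-selection tools), the standard
validation metrics (R^2, RMSEC, RMSECV, RMSEP, RPD, bias), and the
pretreatment x wavenumber-window grid search used to choose a model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace, field
from typing import Sequence

import numpy as np

from . import pls_core, preprocess
from .spectra_io import Dataset, subset_windows

__all__ = [
    "ModelMetrics",
    "GridSpec",
    "GridResult",
    "split_random",
    "boxcar_select",
    "metrics",
    "grid_search",
    "evaluate_cell",
    "DEFAULT_WINDOW_SETS",
    "DEFAULT_PIPELINE_LABELS",
]

log = logging.getLogger(__name__)

#: Window sets screened when choosing the modelling range (cm^-1).
DEFAULT_WINDOW_SETS: dict[str, list[list[float]]] = {
    "4000-5000": [[4000.0, 5000.0]],
    "5000-5400": [[5000.0, 5400.0]],
    "5600-6200": [[5600.0, 6200.0]],
    "6800-7400": [[6800.0, 7400.0]],
    "8200-9000": [[8200.0, 9000.0]],
    "5200-6700; 7700-8800": [[5200.0, 6700.0], [7700.0, 8800.0]],
}

#: Pretreatment pipelines screened by default (scatter correction x derivative).
DEFAULT_PIPELINE_LABELS: list[str] = [
    "MSC + Spectrum",
    "MSC + FD",
    "MSC + SD",
    "MSC + FD + SG",
    "MSC + SD + SG",
    "SNV + Spectrum",
    "SNV + FD",
    "SNV + SD",
    "SNV + FD + SG",
    "SNV + SD + SG",
]


@dataclass(frozen=True)
class ModelMetrics:
    """Calibration/validation figures of merit for one candidate model.

    r2 is computed on fitted calibration predictions, r2_cv on
    leave-one-out predictions; rpd = sd(y_validation; n-1) / RMSEP.
    All errors are in % w/w.
    """

    r2: float
    r2_cv: float
    rmsec: float
    rmsecv: float
    rmsep: float
    rpd: float
    bias: float

    def table_row(self) -> dict:
        return {
            "R2": round(self.r2_cv, 5),
            "RMSECV": round(self.rmsecv, 4),
            "RMSEP": round(self.rmsep, 4),
            "RPD": round(self.rpd, 4),
        }


@dataclass(frozen=True)
class GridSpec:
    """Pretreatment labels x window-set labels x maximum factor count."""

    pipelines: dict[str, list[preprocess.PreprocessStep]]
    window_sets: dict[str, list[list[float]]]
    a_max: int = 10

    def __post_init__(self) -> None:
        if not self.pipelines or not self.window_sets:
            raise ValueError("grid needs at least one pipeline and one window set")

    @classmethod
    def default(cls, a_max: int = 10) -> "GridSpec":
        return cls(
            pipelines={
                lab: preprocess.pipeline_from_label(lab)
                for lab in DEFAULT_PIPELINE_LABELS
            },
            window_sets=dict(DEFAULT_WINDOW_SETS),
            a_max=a_max,
        )


@dataclass
class GridResult:
    """Ranked grid rows: ascending RMSECV, ties broken by descending R^2."""

    rows: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def rank(self) -> None:
        self.rows.sort(key=lambda r: (r["metrics"].rmsecv, -r["metrics"].r2_cv))

    def best(self) -> dict:
        if not self.rows:
            raise ValueError("grid produced no successful rows")
        return self.rows[0]


def split_random(dataset: Dataset, n_calibration: int, seed: int) -> Dataset:
    """Assign calibration/validation roles uniformly at random.

    A pure function of (sample ids, n_calibration, seed): the same seed
    always reproduces the same assignment.
    """
    n = dataset.spectra.n_samples
    if not 0 < n_calibration < n:
        raise ValueError(f"n_calibration must be in (0, {n}), got {n_calibration}")
    rng = np.random.default_rng(seed)
    cal = set(rng.choice(n, size=n_calibration, replace=False).tolist())
    records = [
        replace(r, role="calibration" if i in cal else "validation")
        for i, r in enumerate(dataset.records)
    ]
    return Dataset(dataset.spectra, records)


def _allocate_even(avail: np.ndarray, target: int) -> np.ndarray:
    """Allocate `target` picks over bins as evenly as availability allows.

    Greedy: always top up the least-filled bin that still has members,
    breaking ties toward the fullest remaining bin. Among bins that are
    not exhausted the final counts differ by at most one.
    """
    alloc = np.zeros(avail.size, dtype=int)
    for _ in range(target):
        headroom = avail - alloc
        if headroom.max() <= 0:
            raise ValueError("not enough pool samples to reach the target")
        open_bins = np.flatnonzero(headroom > 0)
        order = open_bins[np.lexsort((-headroom[open_bins], alloc[open_bins]))]
        alloc[order[0]] += 1
    return alloc


def boxcar_select(
    contents: Sequence[float], n_target: int, n_bins: int = 10, seed: int = 0
) -> np.ndarray:
    """Select indices so contents are near-uniform ("boxcar") over their range.

    The content range is cut into `n_bins` equal-width bins; picks are
    spread as evenly over bins as the pool allows, with shortfalls from
    sparse bins redistributed to the fullest remaining bins, and the
    within-bin choice seeded-random. Returns sorted indices.
    """
    y = np.asarray(contents, dtype=float)
    if n_target > y.size:
        raise ValueError(f"n_target={n_target} exceeds pool size {y.size}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_target == y.size:
        return np.arange(y.size)
    edges = np.linspace(y.min(), y.max(), n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, n_bins - 1)
    avail = np.bincount(bin_of, minlength=n_bins)
    alloc = _allocate_even(avail, n_target)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for b in range(n_bins):
        members = np.flatnonzero(bin_of == b)
        if alloc[b]:
            chosen.extend(rng.choice(members, size=alloc[b], replace=False).tolist())
    return np.sort(np.asarray(chosen, dtype=int))


def metrics(
    y_cal: np.ndarray,
    yhat_cal: np.ndarray,
    y_val: np.ndarray,
    yhat_val: np.ndarray,
    rmsecv: float,
    press: float | None = None,
) -> ModelMetrics:
    """Assemble the standard figures of merit from paired predictions."""
    y_cal, yhat_cal = np.asarray(y_cal, float), np.asarray(yhat_cal, float)
    y_val, yhat_val = np.asarray(y_val, float), np.asarray(yhat_val, float)
    if y_cal.size == 0 or y_cal.size != yhat_cal.size or y_val.size != yhat_val.size:
        raise ValueError("prediction vectors must be nonempty and paired")
    sstot = float(((y_cal - y_cal.mean()) ** 2).sum())
    if sstot == 0:
        raise ValueError("calibration contents have zero variance; R^2 undefined")
    r2 = 1.0 - float(((y_cal - yhat_cal) ** 2).sum()) / sstot
    r2_cv = float("nan") if press is None else 1.0 - press / sstot
    rmsec = float(np.sqrt(((y_cal - yhat_cal) ** 2).mean()))
    if y_val.size:
        rmsep = float(np.sqrt(((y_val - yhat_val) ** 2).mean()))
        bias = float((yhat_val - y_val).mean())
        sd_val = float(y_val.std(ddof=1)) if y_val.size > 1 else float("nan")
        rpd = float("inf") if rmsep == 0 else sd_val / rmsep
    else:
        rmsep = bias = rpd = float("nan")
    return ModelMetrics(
        r2=r2, r2_cv=r2_cv, rmsec=rmsec, rmsecv=float(rmsecv),
        rmsep=rmsep, rpd=rpd, bias=bias,
    )


def evaluate_cell(
    dataset: Dataset,
    steps: Sequence[preprocess.PreprocessStep],
    windows: Sequence[Sequence[float]],
    a_max: int = 10,
    tolerance_fraction: float = 0.02,
) -> tuple[ModelMetrics, pls_core.PLSModel, preprocess.PreprocessPipeline, pls_core.CVResult]:
    """Run one pipeline x window cell end to end.

    Cuts windows, fits the pretreatment pipeline on the calibration
    role only, selects the factor count by LOO cross-validation, fits
    the final model and scores the validation role.
    """
    cal = dataset.subset_role("calibration")
    val = dataset.subset_role("validation")
    if cal.spectra.n_samples == 0:
        raise ValueError("dataset has no calibration role assigned")
    y_cal, y_val = cal.contents, (val.contents if val.records else np.empty(0))
    if y_val.size and (
        y_val.min() < y_cal.min() - 1e-12 or y_val.max() > y_cal.max() + 1e-12
    ):
        warnings.warn(
            "validation contents fall outside the calibration content range; "
            "predictions there are extrapolations",
            stacklevel=2,
        )
    cal_w = subset_windows(cal.spectra, windows)
    pipe = preprocess.PreprocessPipeline(list(steps)).fit(cal_w)
    Xc = pipe.transform(cal_w)
    a_cap = min(a_max, cal_w.n_points, cal_w.n_samples - 2)
    curve = pls_core.rmsecv_curve(Xc, y_cal, a_cap, tolerance_fraction)
    model = pls_core.fit_pls1_nipals(Xc, y_cal, curve.chosen_a)
    yhat_cal = pls_core.predict(model, Xc)
    if val.records:
        Xv = pipe.transform(subset_windows(val.spectra, windows))
        yhat_val = pls_core.predict(model, Xv)
    else:
        yhat_val = np.empty(0)
    a_idx = curve.chosen_a - 1
    m = metrics(
        y_cal, yhat_cal, y_val, yhat_val,
        rmsecv=float(curve.rmsecv[a_idx]),
        press=float(curve.press[a_idx]),
    )
    return m, model, pipe, curve


def grid_search(dataset: Dataset, grid: GridSpec) -> GridResult:
    """Evaluate every pipeline x window-set cell; rank by RMSECV.

    Individual cell failures are recorded in `failures` rather than
    aborting the rest of the grid.
    """
    result = GridResult()
    for plabel, steps in grid.pipelines.items():
        for wlabel, windows in grid.window_sets.items():
            try:
                m, model, pipe, curve = evaluate_cell(
                    dataset, steps, windows, grid.a_max
                )
            except Exception as exc:  # noqa: BLE001 - per-cell isolation
                log.warning("grid cell (%s | %s) failed: %s", plabel, wlabel, exc)
                result.failures.append(
                    {"pipeline": plabel, "windows": wlabel, "error": str(exc)}
                )
                continue
            result.rows.append(
                {
                    "pipeline": plabel,
                    "windows": wlabel,
                    "chosen_a": curve.chosen_a,
                    "metrics": m,
                }
            )
    result.rank()
    return result
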