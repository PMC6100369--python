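"""NIPALS PLS1 regression with leave-one-out cross-validation.

The calibration model is partial least squares with a single response
(content, % w/w). Factors are extracted by NIPALS: for mean-centred
X (n x p) and y,

    w_k = X'y / ||X'y||        (weight, unit norm)
    t_k = X w_k                (score)
    p_k = X't_k / (t_k't_k)    (x-loading)
    q_k = y't_k / (t_k't_k)    (y-loading)
    X <- X - t_k p_k',  y <- y - q_k t_k   (deflation)

after which the regression vector is b = W (P'W)^-1 q and predictions
are y_mean + (X - x_mean) b. For a single response no iteration is
needed within a factor, so the fit is exactly deterministic.

Factor count is chosen from leave-one-out cross-validation: PRESS(a)
is the sum of squared LOO prediction errors with a factors, RMSECV =
sqrt(PRESS / n), and the retained a is the smallest whose RMSECV is
within a small fraction (default 2%) of the curve minimum — the usual
parsimony guard against overfitting with too many latent factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra_io import SpectrumSet

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls1_nipals",
    "predict",
    "loo_rmsecv",
    "rmsecv_curve",
    "select_factors",
    "save_model",
    "load_model",
]

_RESIDUAL_VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class PLSModel:
    """Fitted NIPALS PLS1 state."""

    n_factors: int
    x_mean: np.ndarray          # p
    y_mean: float
    weights: np.ndarray         # p x a, unit-norm columns
    x_loadings: np.ndarray      # p x a
    y_loadings: np.ndarray      # a
    regression_vector: np.ndarray  # p

    @property
    def n_points(self) -> int:
        return self.x_mean.size


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    Xm = X.absorbance if isinstance(X, SpectrumSet) else np.asarray(X, float)
    yv = np.asarray(y, dtype=float)
    if Xm.shape[0] != yv.size:
        raise ValueError("X rows and y length differ")
    return Xm, yv


def _nipals(Xc: np.ndarray, yc: np.ndarray, a: int) -> tuple[np.ndarray, ...]:
    n, p = Xc.shape
    y0var = float(yc @ yc)
    W = np.zeros((p, a))
    P = np.zeros((p, a))
    q = np.zeros(a)
    X, y = Xc.copy(), yc.copy()
    extracted = 0
    for k in range(a):
        if float(y @ y) < _RESIDUAL_VARIANCE_FLOOR * max(y0var, 1.0):
            break  # response exhausted; keep the factors extracted so far
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-300:
            break
        pk = X.T @ t / tt
        qk = float(y @ t) / tt
        W[:, k], P[:, k], q[k] = w, pk, qk
        X = X - np.outer(t, pk)
        y = y - qk * t
        extracted += 1
    return W[:, :extracted], P[:, :extracted], q[:extracted]


def fit_pls1_nipals(X, y, a: int) -> PLSModel:
    """Fit a PLS1 model with `a` latent factors by NIPALS.

    X may be a SpectrumSet or a plain matrix; y is the content vector
    in % w/w. Columns of X and y are mean-centred; spectra are not
    autoscaled. If the response is exhausted before `a` factors the
    model records the factors actually extracted.
    """
    Xm, yv = _as_xy(X, y)
    n, p = Xm.shape
    if a < 1:
        raise ValueError("need at least one factor")
    if n < a + 1:
        raise ValueError(f"need at least a+1={a + 1} samples for a={a} factors")
    if np.var(yv) == 0:
        raise ValueError("y has zero variance")
    x_mean = Xm.mean(axis=0)
    y_mean = float(yv.mean())
    W, P, q = _nipals(Xm - x_mean, yv - y_mean, min(a, p))
    if W.shape[1] == 0:
        raise ValueError("no PLS factor could be extracted")
    # b = W (P'W)^{-1} q ; P'W is upper triangular with unit diagonal
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_factors=W.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=b,
    )


def predict(model: PLSModel, X) -> np.ndarray:
    """Predict contents (% w/w): y_mean + (X - x_mean) b."""
    Xm = X.absorbance if isinstance(X, SpectrumSet) else np.asarray(X, float)
    if Xm.ndim == 1:
        Xm = Xm[None, :]
    if Xm.shape[1] != model.n_points:
        raise ValueError(
            f"spectra have {Xm.shape[1]} points, model expects {model.n_points}"
        )
    return model.y_mean + (Xm - model.x_mean) @ model.regression_vector


def _loo_press_all(Xm: np.ndarray, yv: np.ndarray, a_max: int) -> np.ndarray:
    """LOO squared-error matrix (n x a_max) by honest refits.

    Each sample is held out in turn and a fresh model (including
    re-centring) is fitted on the remainder; predictions at every
    factor count 1..a_max come from one NIPALS pass per held-out
    sample, accumulating the score-space predictions factor by factor.
    """
    n, p = Xm.shape
    err2 = np.full((n, a_max), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = Xm[mask], yv[mask]
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        W, P, q = _nipals(Xt - x_mean, yt - y_mean, min(a_max, p, n - 2))
        k = W.shape[1]
        # accumulate prediction over factors for the held-out spectrum
        x = Xm[i] - x_mean
        yhat = y_mean
        for j in range(a_max):
            if j < k:
                t = float(x @ W[:, j])
                yhat = yhat + q[j] * t
                x = x - t * P[:, j]
            err2[i, j] = (yhat - yv[i]) ** 2
    return err2


def loo_rmsecv(X, y, a: int) -> tuple[float, float]:
    """Leave-one-out PRESS and RMSECV at a fixed factor count.

    PRESS = sum_i (yhat_(i) - y_i)^2 over honest refits; RMSECV =
    sqrt(PRESS / n), reported in % w/w.
    """
    Xm, yv = _as_xy(X, y)
    n = Xm.shape[0]
    if n < a + 2:
        raise ValueError("need at least a+2 samples for leave-one-out")
    press = float(_loo_press_all(Xm, yv, a)[:, a - 1].sum())
    return press, float(np.sqrt(press / n))


@dataclass(frozen=True)
class CVResult:
    """Per-factor-count PRESS/RMSECV table with the selected count."""

    factors: np.ndarray   # 1..a_max
    press: np.ndarray     # squared % w/w
    rmsecv: np.ndarray    # % w/w
    chosen_a: int

    def as_rows(self) -> list[dict]:
        return [
            {"a": int(a), "press": float(p), "rmsecv": float(r)}
            for a, p, r in zip(self.factors, self.press, self.rmsecv)
        ]


def select_factors(rmsecv: np.ndarray, tolerance_fraction: float = 0.02) -> int:
    """Smallest factor count with RMSECV within (1+tol) of the minimum."""
    r = np.asarray(rmsecv, dtype=float)
    if r.size == 0:
        raise ValueError("empty RMSECV curve")
    threshold = (1.0 + tolerance_fraction) * r.min()
    return int(np.flatnonzero(r <= threshold)[0]) + 1


def rmsecv_curve(X, y, a_max: int = 10, tolerance_fraction: float = 0.02) -> CVResult:
    """LOO PRESS/RMSECV for a = 1..a_max plus the parsimonious choice."""
    Xm, yv = _as_xy(X, y)
    n, p = Xm.shape
    if a_max > min(n - 2, p):
        raise ValueError(f"a_max={a_max} exceeds min(n-2, p)={min(n - 2, p)}")
    press = _loo_press_all(Xm, yv, a_max).sum(axis=0)
    rmsecv = np.sqrt(press / n)
    return CVResult(
        factors=np.arange(1, a_max + 1),
        press=press,
        rmsecv=rmsecv,
        chosen_a=select_factors(rmsecv, tolerance_fraction),
    )


_FORMAT_VERSION = 1


def save_model(
    model: PLSModel,
    path: str | Path,
    *,
    axis: np.ndarray | None = None,
    windows: list | None = None,
    pipeline_spec: list | None = None,
    msc_references: dict | None = None,
) -> None:
    """Serialise a model (plus its preprocessing context) to JSON."""
    doc = {
        "format": "nirquant-pls-model",
        "version": _FORMAT_VERSION,
        "n_factors": model.n_factors,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "regression_vector": model.regression_vector.tolist(),
        "axis": None if axis is None else np.asarray(axis).tolist(),
        "windows": windows,
        "pipeline": pipeline_spec,
        "msc_references": None
        if msc_references is None
        else {str(k): np.asarray(v).tolist() for k, v in msc_references.items()},
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> tuple[PLSModel, dict]:
    """Load a serialised model; returns (model, context dict)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "nirquant-pls-model":
        raise ValueError(f"{path}: not a nirquant PLS model file")
    if doc.get("version") != _FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format version")
    model = PLSModel(
        n_factors=int(doc["n_factors"]),
        x_mean=np.asarray(doc["x_mean"], float),
        y_mean=float(doc["y_mean"]),
        weights=np.asarray(doc["weights"], float),
        x_loadings=np.asarray(doc["x_loadings"], float),
        y_loadings=np.asarray(doc["y_loadings"], float),
        regression_vector=np.asarray(doc["regression_vector"], float),
    )
    context = {
        "axis": None if doc["axis"] is None else np.asarray(doc["axis"], float),
        "windows": doc["windows"],
        "pipeline": doc["pipeline"],
        "msc_references": None
        if doc["msc_references"] is None
        else {int(k): np.asarray(v, float) for k, v in doc["msc_references"].items()},
    }
    return model, context
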