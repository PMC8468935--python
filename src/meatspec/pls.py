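"""Partial least squares regression (univariate response, NIPALS).

The algorithm mean-centres X and y, then per component computes

    w = X'y / ||X'y||,  t = Xw,  p = X't / t't,  q = y't / t't

and deflates ``X <- X - t p'``, ``y <- y - q t``.  The composite regression
vector on centred data is ``b = W (P'W)^{-1} q``, so prediction is
``y_hat = y_mean + (X_new - x_mean) b``.  Latent-variable counts are chosen
by leave-one-out cross-validation at the minimum RMSECV (first index on
ties).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PLSRModel",
    "CVResult",
    "fit_plsr",
    "predict",
    "select_components",
    "save_model",
    "load_model",
]

_TINY = 1e-12


@dataclass
class PLSRModel:
    """Fitted PLSR model (centred-data coefficients plus centring vectors)."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray        # p x k (columns are w_i)
    x_loadings: np.ndarray     # p x k
    y_loadings: np.ndarray     # k
    coefficients: np.ndarray   # p
    n_components: int
    property_name: str = ""
    x_scale: np.ndarray | None = None
    scores: np.ndarray | None = field(default=None, repr=False)  # n x k (training)

    def __post_init__(self) -> None:
        k = self.n_components
        if not (self.weights.shape[1] == self.x_loadings.shape[1]
                == self.y_loadings.size == k):
            raise ValueError("component arrays disagree on n_components")


@dataclass
class CVResult:
    """LOOCV error per candidate component count and the chosen count."""

    rmsecv: np.ndarray            # index k-1 -> RMSECV at k components (nan = invalid)
    n_components: int

    def __post_init__(self) -> None:
        valid = np.where(np.isfinite(self.rmsecv))[0]
        if valid.size == 0:
            raise ValueError("no valid component count")
        best = valid[np.argmin(self.rmsecv[valid])] + 1
        if best != self.n_components:
            raise ValueError("chosen n_components does not minimise RMSECV")


def _center(X: np.ndarray, y: np.ndarray, scale: bool):
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    x_scale = None
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale < _TINY] = 1.0
        Xc = Xc / x_scale
    return Xc, y - y_mean, x_mean, y_mean, x_scale


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, max_components: int, warn: bool = True):
    """Run NIPALS, returning (W, P, q, T, B_path) with B_path[:, k-1] the
    centred-data coefficient vector using k components."""
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W, P, Q, T = [], [], [], []
    for _ in range(max_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < _TINY:
            if warn:
                warnings.warn("NIPALS stopped early: residual covariance vanished",
                              stacklevel=3)
            break
        w = w / nw
        t = X @ w
        tt = float(t @ t)
        if np.sqrt(tt) < _TINY:
            if warn:
                warnings.warn("NIPALS stopped early: score norm below tolerance",
                              stacklevel=3)
            break
        pvec = X.T @ t / tt
        q = float(y @ t) / tt
        X -= np.outer(t, pvec)
        y = y - q * t
        W.append(w); P.append(pvec); Q.append(q); T.append(t)
    k = len(W)
    if k == 0:
        raise ValueError("could not extract any PLS component")
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.array(Q)
    Tm = np.column_stack(T)
    # P'W is unit upper triangular for univariate-y NIPALS; solve generically
    # for numerical robustness.
    PtW = Pm.T @ Wm
    B = np.empty((Xc.shape[1], k))
    for j in range(1, k + 1):
        sol = np.linalg.solve(PtW[:j, :j], qv[:j])
        B[:, j - 1] = Wm[:, :j] @ sol
    return Wm, Pm, qv, Tm, B


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    property_name: str = "",
    scale: bool = False,
) -> PLSRModel:
    """Fit a univariate-y PLSR model with the requested component count.

    Fewer components are returned (with a warning) if the score norm
    collapses before ``n_components`` is reached.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X rows and y length differ")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, columns)={min(n - 1, p)}"
        )
    if float(np.var(y)) < _TINY:
        raise ValueError("response has zero variance")

    Xc, yc, x_mean, y_mean, x_scale = _center(X, y, scale)
    W, P, q, T, B = _nipals_path(Xc, yc, n_components)
    k = W.shape[1]
    coef = B[:, k - 1]
    if x_scale is not None:
        coef = coef / x_scale
    return PLSRModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P, y_loadings=q,
        coefficients=coef, n_components=k, property_name=property_name,
        x_scale=x_scale, scores=T,
    )


def predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the response: ``y_mean + (X_new - x_mean) . b``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; model expects {model.x_mean.size}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.coefficients


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 15,
    scale: bool = False,
) -> CVResult:
    """Choose the component count by leave-one-out cross-validation.

    For every candidate count k the left-out sample of each fold is
    predicted by a model refitted without it; the chosen count minimises
    RMSECV (smallest count on ties).  Counts that some fold cannot reach
    are marked invalid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    kmax = min(max_components, n - 2, p)
    if kmax < 1:
        raise ValueError("too few samples for LOOCV component selection")

    preds = np.full((n, kmax), np.nan)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        mask[i] = True
        try:
            Xc, yc, x_mean, y_mean, x_scale = _center(Xi, yi, scale)
            *_, B = _nipals_path(Xc, yc, kmax, warn=False)
        except ValueError:
            continue  # fold failed entirely; all k stay invalid for it
        xrow = X[i] - x_mean
        if x_scale is not None:
            xrow = xrow / x_scale
        ki = B.shape[1]
        preds[i, :ki] = y_mean + xrow @ B

    valid = ~np.isnan(preds).any(axis=0)
    if not valid.any():
        raise ValueError("LOOCV failed for every candidate component count")
    rmsecv = np.full(kmax, np.nan)
    resid = preds - y[:, None]
    rmsecv[valid] = np.sqrt(np.mean(resid[:, valid] ** 2, axis=0))
    best = int(np.nanargmin(np.where(valid, rmsecv, np.inf))) + 1
    return CVResult(rmsecv=rmsecv, n_components=best)


# ----------------------------------------------------------------------
# Plain-text model serialisation


def save_model(model: PLSRModel, path: str | Path, extra: dict | None = None) -> None:
    payload = {
        "format": "meatspec-plsr-v1",
        "property_name": model.property_name,
        "n_components": model.n_components,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "coefficients": model.coefficients.tolist(),
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "x_scale": None if model.x_scale is None else model.x_scale.tolist(),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> tuple[PLSRModel, dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "meatspec-plsr-v1":
        raise ValueError(f"{path} is not a recognised model file")
    model = PLSRModel(
        x_mean=np.array(payload["x_mean"], dtype=float),
        y_mean=float(payload["y_mean"]),
        weights=np.array(payload["weights"], dtype=float),
        x_loadings=np.array(payload["x_loadings"], dtype=float),
        y_loadings=np.array(payload["y_loadings"], dtype=float),
        coefficients=np.array(payload["coefficients"], dtype=float),
        n_components=int(payload["n_components"]),
        property_name=payload.get("property_name", ""),
        x_scale=None if payload.get("x_scale") is None
        else np.array(payload["x_scale"], dtype=float),
    )
    return model, payload
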