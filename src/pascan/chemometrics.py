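"""From-scratch multivariate calibration: PLSR (NIPALS), PCR, and LOO-CV.

Spectral glucose calibration is an ill-posed regression: a few dozen
spectra with hundreds of wavenumber channels.  Partial least squares
regression projects both the spectra ``X`` and the reference glucose ``y``
onto a small number of latent variables chosen to maximize their
covariance; principal component regression projects ``X`` onto its leading
principal components and regresses ``y`` on the scores.  Both are
implemented here directly (the NIPALS PLS1 recursion and an SVD-based PCR)
rather than wrapped from a library, since the calibration procedure is the
point of the package.  Model selection uses leave-one-out cross-validation
with re-centering inside every fold, choosing the latent-variable count at
the global RMSE-CV minimum (smallest count on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .synthetic_skin import WavenumberGrid

__all__ = [
    "CalibrationSet",
    "PLSRModel",
    "PCRModel",
    "CVResult",
    "mean_center",
    "fit_plsr",
    "fit_pcr",
    "predict",
    "loo_cv",
    "select_n_lv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationSet:
    """Paired spectra and reference glucose values for one probing site."""

    X: np.ndarray                 # (n_samples, n_wavenumbers), normalized spectra
    y: np.ndarray                 # (n_samples,), reference glucose in mg/dl
    grid: WavenumberGrid | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per entry of y")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("calibration data must be finite")
        if self.grid is not None and X.shape[1] != len(self.grid):
            raise ValueError("X column count must match the wavenumber grid")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def mean_center(X, y=None):
    """Column-center X and center y; returns (Xc, yc, x_mean, y_mean)."""
    X = np.asarray(X, dtype=float)
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    if y is None:
        return Xc, None, x_mean, None
    y = np.asarray(y, dtype=float)
    y_mean = float(y.mean())
    return Xc, y - y_mean, x_mean, y_mean


@dataclass(frozen=True)
class PLSRModel:
    """Fitted PLS1 model (univariate response).

    ``W`` holds the X-weights, ``P`` the X-loadings, ``T`` the training
    scores, ``q`` the response loadings per latent variable; ``b`` is the
    collapsed regression vector so that predictions are
    ``(X - x_mean) @ b + y_mean``.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray          # (p, a)
    P: np.ndarray          # (p, a)
    T: np.ndarray          # (n, a)
    q: np.ndarray          # (a,)
    b: np.ndarray          # (p,)
    n_lv: int

    def predict(self, X_new) -> np.ndarray:
        return predict(self, X_new)


@dataclass(frozen=True)
class PCRModel:
    """Principal-component regression model with the same prediction contract."""

    x_mean: np.ndarray
    y_mean: float
    b: np.ndarray
    n_pc: int
    singular_values: np.ndarray

    def predict(self, X_new) -> np.ndarray:
        return predict(self, X_new)


def _usable_components(Xc: np.ndarray) -> int:
    n = Xc.shape[0]
    return int(min(n - 1, np.linalg.matrix_rank(Xc))) if n > 1 else 0


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, a_max: int):
    """NIPALS PLS1 recursion; returns (W, P, T, q, B) for 1..a_max components.

    Per component: ``w = X'y / ||X'y||``, ``t = X w``, ``p = X't / t't``,
    ``q = y't / t't``, then deflate ``X -= t p'`` and ``y -= q t``.  The
    coefficient vector for ``a`` components is ``W_a (P_a' W_a)^-1 q_a``;
    ``B[:, a-1]`` stores it for each count.
    """
    X = Xc.copy()
    y = yc.copy()
    n, p = X.shape
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    T = np.zeros((n, a_max))
    q = np.zeros(a_max)
    B = np.zeros((p, a_max))
    for a in range(a_max):
        w = X.T @ y
        norm_w = np.linalg.norm(w)
        if norm_w <= 1e-12:
            # Krylov breakdown: no covariance left to extract
            a_max = a
            W, P, T, q, B = W[:, :a], P[:, :a], T[:, :a], q[:a], B[:, :a]
            break
        w /= norm_w
        t = X @ w
        tt = float(t @ t)
        p_vec = X.T @ t / tt
        q_a = float(y @ t / tt)
        X -= np.outer(t, p_vec)
        y -= q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_vec, t, q_a
        B[:, a] = W[:, : a + 1] @ np.linalg.solve(
            P[:, : a + 1].T @ W[:, : a + 1], q[: a + 1]
        )
    return W, P, T, q, B


def fit_plsr(X, y, n_lv: int) -> PLSRModel:
    """Fit a PLS1 model with ``n_lv`` latent variables (NIPALS).

    ``n_lv`` may not exceed ``min(n_samples - 1, rank(centered X))``; the
    error message reports the attainable maximum.  The fit is fully
    deterministic.
    """
    Xc, yc, x_mean, y_mean = mean_center(X, y)
    usable = _usable_components(Xc)
    if not 1 <= n_lv <= usable:
        raise ValueError(
            f"n_lv must be between 1 and {usable} (min of n_samples - 1 and rank)"
        )
    W, P, T, q, B = _nipals_path(Xc, yc, n_lv)
    return PLSRModel(
        x_mean=x_mean, y_mean=y_mean, W=W, P=P, T=T, q=q, b=B[:, n_lv - 1], n_lv=n_lv
    )


def fit_pcr(X, y, n_pc: int) -> PCRModel:
    """Principal-component regression: SVD of centered X, regress y on scores."""
    Xc, yc, x_mean, y_mean = mean_center(X, y)
    usable = _usable_components(Xc)
    if not 1 <= n_pc <= usable:
        raise ValueError(
            f"n_pc must be between 1 and {usable} (min of n_samples - 1 and rank)"
        )
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    coef_scores = (U[:, :n_pc].T @ yc) / s[:n_pc]
    b = Vt[:n_pc].T @ coef_scores
    return PCRModel(
        x_mean=x_mean, y_mean=y_mean, b=b, n_pc=n_pc, singular_values=s[:n_pc]
    )


def predict(model, X_new) -> np.ndarray:
    """Predict glucose: ``(X_new - x_mean) @ b + y_mean``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; model was trained with "
            f"{model.x_mean.size}"
        )
    return (X_new - model.x_mean) @ model.b + model.y_mean


@dataclass(frozen=True)
class CVResult:
    """Leave-one-out cross-validation outcome over candidate component counts."""

    y_cv: np.ndarray            # LOO predictions at the chosen count
    y_cv_by_lv: np.ndarray      # (n_samples, n_candidates)
    rmsecv_by_lv: np.ndarray
    rmsec_by_lv: np.ndarray
    chosen_lv: int


def select_n_lv(rmsecv_by_lv) -> int:
    """Latent-variable count at the global RMSE-CV minimum (smallest on ties)."""
    curve = np.asarray(rmsecv_by_lv, dtype=float)
    if curve.size == 0:
        raise ValueError("RMSE-CV curve must not be empty")
    chosen = int(np.argmin(curve)) + 1
    if chosen == curve.size and curve.size > 1:
        logger.warning(
            "RMSE-CV still decreasing at the largest candidate count (%d); "
            "consider extending the range", chosen,
        )
    return chosen


def loo_cv(X, y, max_lv: int, method: str = "plsr") -> CVResult:
    """Leave-one-out cross-validation over 1..max_lv components.

    Each fold re-centers on its training samples (no leakage), fits the
    whole component path once, and predicts the held-out spectrum at every
    candidate count.  RMSEC comes from full-data fits.  If ``max_lv`` is
    infeasible in any fold the range is capped with a logged note.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("leave-one-out CV needs at least 3 samples")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if method not in ("plsr", "pcr"):
        raise ValueError("method must be 'plsr' or 'pcr'")

    def coef_path(Xc, yc, a_max):
        if method == "plsr":
            return _nipals_path(Xc, yc, a_max)[4]
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        B = np.zeros((Xc.shape[1], a_max))
        coef_scores = np.zeros(a_max)
        for a in range(a_max):
            coef_scores[a] = (U[:, a] @ yc) / s[a]
            B[:, a] = Vt[: a + 1].T @ coef_scores[: a + 1]
        return B

    cap = max_lv
    folds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xc, yc, xm, ym = mean_center(X[mask], y[mask])
        usable = _usable_components(Xc)
        cap = min(cap, usable)
        folds.append((i, Xc, yc, xm, ym))
    if cap < max_lv:
        logger.warning(
            "requested max_lv=%d infeasible in at least one fold; capped at %d",
            max_lv, cap,
        )
    if cap < 1:
        raise ValueError("cross-validation folds are rank-deficient; no component fits")

    y_cv_by_lv = np.empty((n, cap))
    for i, Xc, yc, xm, ym in folds:
        B = coef_path(Xc, yc, cap)
        y_cv_by_lv[i] = (X[i] - xm) @ B + ym
    rmsecv = np.sqrt(np.mean((y_cv_by_lv - y[:, None]) ** 2, axis=0))

    Xc, yc, xm, ym = mean_center(X, y)
    B_full = coef_path(Xc, yc, min(cap, _usable_components(Xc)))
    fitted = Xc @ B_full + ym
    rmsec = np.sqrt(np.mean((fitted - y[:, None]) ** 2, axis=0))
    if rmsec.size < cap:  # full-data rank below fold cap: pad with the last value
        rmsec = np.concatenate([rmsec, np.full(cap - rmsec.size, rmsec[-1])])

    chosen = select_n_lv(rmsecv)
    return CVResult(
        y_cv=y_cv_by_lv[:, chosen - 1],
        y_cv_by_lv=y_cv_by_lv,
        rmsecv_by_lv=rmsecv,
        rmsec_by_lv=rmsec,
        chosen_lv=chosen,
    )
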