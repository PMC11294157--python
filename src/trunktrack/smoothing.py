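"""Woltring-style smoothing: quintic spline penalising the third derivative.

The smoother solves, per coordinate,

    min_f  sum_i (y_i - f(t_i))^2  +  lambda * int f'''(t)^2 dt

over quintic splines, and picks a single ``lambda`` per trajectory so
that the trace-corrected residual estimate of the measurement error,
pooled over the trajectory's coordinates,

    sigma_hat^2(lambda) = RSS(lambda) / (d * (n - tr A(lambda))),

matches a user-specified *predicted mean squared error* (study value:
10 mm^2).  ``A(lambda)`` is the hat matrix.  Quadratic trajectories lie in
the null space of the penalty and are reproduced exactly at any smoothing
level; ``predicted_mse = 0`` returns the interpolating spline.

Implementation: a quintic B-spline basis with interpolation knots gives a
square, invertible design matrix ``B``.  With ``B^T B = L L^T`` and the
eigendecomposition ``L^{-1} Omega L^{-T} = U diag(gamma) U^T`` of the
third-derivative penalty ``Omega`` (the Demmler-Reinsch basis),

    w = U^T L^{-1} B^T y,
    RSS(lambda)  = sum w_i^2 (lambda g_i / (1 + lambda g_i))^2,
    tr A(lambda) = sum 1 / (1 + lambda g_i),

so the search over ``lambda`` is O(n) per evaluation.  The factorisation
depends only on the time grid and is cached per (n, dt), which makes
smoothing whole cohorts cheap.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline, make_interp_spline
from scipy.linalg import cho_factor, cho_solve, eigh, solve_triangular
from scipy.optimize import brentq

from .errors import ConfigError, NonUniformSampling, TooShortSeries
from .trial import MarkerTrialSet

SPLINE_DEGREE = 5         # quintic
PENALTY_DERIVATIVE = 3    # Woltring GCVSPL mode: third-derivative penalty
MIN_FRAMES = 12
_REL_TOL = 0.01           # residual-matching tolerance (relative)


@dataclass(frozen=True)
class SmoothingConfig:
    """Predicted mean squared error (mm^2) of the marker measurement noise."""

    predicted_mse: float = 10.0

    def __post_init__(self):
        if self.predicted_mse < 0:
            raise ConfigError("predicted_mse must be >= 0")


def _derivative_operator(t: np.ndarray, k: int) -> sp.csr_matrix:
    """Sparse map from degree-k coefficients to degree-(k-1) derivative coefs."""
    m = len(t) - k - 1  # number of coefficients at degree k
    denom = t[k + 1:k + m] - t[1:m]
    rows = np.arange(m - 1)
    D = sp.csr_matrix(
        (np.concatenate([-k / denom, k / denom]),
         (np.concatenate([rows, rows]), np.concatenate([rows, rows + 1]))),
        shape=(m - 1, m),
    )
    return D


@lru_cache(maxsize=8)
def _grid_factorisation(n: int, dt: float):
    """Basis, Cholesky and Demmler-Reinsch factors for a uniform time grid."""
    x = np.arange(n) * dt
    t = make_interp_spline(x, np.zeros(n), k=SPLINE_DEGREE).t
    B = BSpline.design_matrix(x, t, SPLINE_DEGREE)  # square (n, n), sparse

    # third-derivative operator: chain of three first-derivative maps
    D = sp.identity(n, format="csr")
    tk = t
    for k in range(SPLINE_DEGREE, SPLINE_DEGREE - PENALTY_DERIVATIVE, -1):
        D = _derivative_operator(tk, k) @ D
        tk = tk[1:-1]
    # Gram matrix of the degree-2 derivative basis by 3-point Gauss quadrature
    k2 = SPLINE_DEGREE - PENALTY_DERIVATIVE
    breaks = np.unique(tk)
    mid = 0.5 * (breaks[1:] + breaks[:-1])
    half = 0.5 * np.diff(breaks)
    nodes, weights = np.polynomial.legendre.leggauss(3)
    G = sp.csr_matrix((len(tk) - k2 - 1, len(tk) - k2 - 1))
    for u, w in zip(nodes, weights):
        P = BSpline.design_matrix(mid + u * half, tk, k2)
        G = G + (P.T.multiply(w * half) @ P)
    omega = (D.T @ G @ D).toarray()

    BtB = (B.T @ B).toarray()
    L = np.linalg.cholesky(BtB)
    Linv_omega = solve_triangular(L, omega, lower=True)
    S = solve_triangular(L, Linv_omega.T, lower=True)
    gamma, U = eigh(0.5 * (S + S.T))
    # eigenvalues at the numerical noise floor are penalty null-space modes
    gamma = np.clip(gamma, 0.0, None)
    gamma[gamma < 1e-13 * gamma.max()] = 0.0
    return B.tocsr(), L, U, gamma


def woltring_smooth(trajectory: np.ndarray, rate: float,
                    config: SmoothingConfig = SmoothingConfig(),
                    t: np.ndarray | None = None) -> np.ndarray:
    """Smooth a uniformly sampled trajectory (n,) or (n, d), returning same shape.

    Raises
    ------
    TooShortSeries
        fewer than 12 frames.
    NonUniformSampling
        if an explicit time vector *t* is supplied and is not uniform.
    """
    y = np.asarray(trajectory, dtype=float)
    squeeze = y.ndim == 1
    y = y.reshape(y.shape[0], -1)
    n = y.shape[0]
    if n < MIN_FRAMES:
        raise TooShortSeries(f"need >= {MIN_FRAMES} frames, got {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("trajectory contains non-finite samples")
    if t is not None:
        steps = np.diff(np.asarray(t, float))
        if steps.size and (steps.max() - steps.min()) > 1e-9 * abs(steps.mean()):
            raise NonUniformSampling("sample times are not uniformly spaced")
    dt = 1.0 / float(rate)
    B, L, U, gamma = _grid_factorisation(n, round(dt, 12))

    # Deflate the exact quadratic component: it lies in the penalty null
    # space, so removing it analytically keeps quadratic trajectories exact
    # even at extreme smoothing levels.
    x01 = np.linspace(-1.0, 1.0, n)
    V = np.polynomial.polynomial.polyvander(x01, 2)
    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    quad = V @ coef
    resid = y - quad

    # One smoothing parameter for the whole trajectory, matched on the
    # residual pooled over coordinates: the smoother is then a single
    # linear operator, which makes it exactly equivariant under rigid
    # rotations (they mix coordinates orthogonally, leaving the pooled
    # residual unchanged).
    z = solve_triangular(L, B.T @ resid, lower=True)
    W = U.T @ z
    lam = _match_predicted_mse(W, gamma, n, config.predicted_mse)
    shrink = 1.0 / (1.0 + lam * gamma)
    C = solve_triangular(L.T, U @ (shrink[:, None] * W), lower=False)
    out = B @ C + quad
    return out[:, 0] if squeeze else out


def _match_predicted_mse(w, gamma, n, target):
    """lambda such that RSS/(d*(n - trA)) matches *target*, clamped to feasibility.

    *w* holds the Demmler-Reinsch coordinates, one column per trajectory
    coordinate; the residual is pooled over columns.
    """
    if target <= 0:
        return 0.0

    w2 = np.atleast_2d((w ** 2).T).sum(axis=0) if w.ndim > 1 else w ** 2
    d = w.shape[1] if w.ndim > 1 else 1

    def sigma_hat2(lam):
        r = lam * gamma / (1.0 + lam * gamma)
        rss = float(np.sum(w2 * r ** 2))
        edf = d * float(np.sum(r))  # d * (n - trA)
        return rss / edf if edf > 0 else 0.0

    gpos = gamma[gamma > 0]
    if gpos.size == 0:
        return 0.0
    lo, hi = 1e-12 / gpos.max(), 1e12 / gpos.min()
    f_lo, f_hi = sigma_hat2(lo) - target, sigma_hat2(hi) - target
    if f_hi <= 0:   # even maximal smoothing under-shoots the target residual
        return hi
    if f_lo >= 0:   # even the near-interpolant over-shoots: least smoothing
        return lo
    s = brentq(lambda s: sigma_hat2(10.0 ** s) - target,
               np.log10(lo), np.log10(hi), xtol=1e-9)
    return 10.0 ** s


def smooth_trial(trial: MarkerTrialSet,
                 config: SmoothingConfig = SmoothingConfig(),
                 max_gap_s: float = 0.1) -> MarkerTrialSet:
    """Smooth every marker trajectory of a trial, respecting occlusion gaps.

    Short interior gaps are linearly interpolated first; frames in longer
    gaps are bridged for the spline fit but re-masked afterwards.
    """
    out = trial.interpolate_gaps(max_gap_s=max_gap_s)
    for name in out.markers:
        mask = out.occluded[name]
        pos = out.positions[name]
        if mask.any():
            good = ~mask
            if good.sum() < MIN_FRAMES:
                continue
            frames = np.arange(out.n_frames)
            filled = pos.copy()
            for axis in range(3):
                filled[mask, axis] = np.interp(
                    frames[mask], frames[good], pos[good, axis])
            smoothed = woltring_smooth(filled, out.rate, config)
            smoothed[mask] = np.nan
            out.positions[name] = smoothed
        else:
            out.positions[name] = woltring_smooth(pos, out.rate, config)
    return out
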