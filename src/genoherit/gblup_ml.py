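"""Maximum-likelihood variance components for the single-GRM mixed model.

The model is ``y ~ N(0, G sigma2_u + I sigma2_e)`` with pre-centered
phenotypes (no fixed effects).  Writing ``h = sigma2_u / (sigma2_u +
sigma2_e)`` and ``lambda = h / (1 - h)``, the covariance is proportional to
``lambda G + I``; after rotating ``y`` into the eigenbasis of ``G`` the
log-likelihood separates coordinate-wise, the total variance profiles out
analytically, and maximisation reduces to a one-dimensional search over
``h`` in ``[0, 1)`` — a coarse grid followed by bounded scalar refinement.

An optional REML mode removes the 1 degree of freedom of an (implicit)
fitted mean by restricting the likelihood to the orthogonal complement of
the intercept; it is off by default because phenotypes are generated
pre-centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from genoherit.grm import GRM

__all__ = ["VarCompFit", "eigendecompose", "profile_loglik", "fit_ml"]

_H_MAX = 1.0 - 1e-6


@dataclass
class VarCompFit:
    """ML estimates of (sigma2_u, sigma2_e) and the heritability ratio."""

    sigma2_u_hat: float
    sigma2_e_hat: float
    h2_u_hat: float
    loglik: float
    n_obs: int
    boundary: bool
    identifiable: bool = True
    optimizer_trace: dict = field(default_factory=dict)


def _as_matrix(G: GRM | np.ndarray) -> np.ndarray:
    return G.matrix if isinstance(G, GRM) else np.asarray(G, dtype=float)


def eigendecompose(
    G: GRM | np.ndarray,
    clip_threshold_scale: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral decomposition ``G = U diag(d) U'`` with eigenvalues >= 0.

    Small negative eigenvalues (round-off from the rank-deficient
    cross-product) are clipped at zero; the clip threshold is
    ``clip_threshold_scale * max(d)``.  Raises on asymmetric input.
    """
    M = _as_matrix(G)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("G must be a square matrix")
    scale = max(np.abs(M).max(), 1.0)
    if np.abs(M - M.T).max() > 1e-8 * scale:
        raise ValueError("G is not symmetric within tolerance")
    d, U = np.linalg.eigh((M + M.T) / 2.0)
    clip = clip_threshold_scale * max(d.max(), 0.0)
    d = np.where(d < clip, 0.0, d)
    return U, d


def profile_loglik(y_rot: np.ndarray, eigvals: np.ndarray, h: float) -> float:
    """Profile log-likelihood at heritability ratio ``h`` (constants dropped).

    With ``lambda = h/(1-h)`` and ``v_i = lambda d_i + 1``, the residual
    variance profiles out as ``sigma2_e(h) = mean(y*_i^2 / v_i)`` and

        l(h) = -1/2 [ sum_i log v_i + n log sigma2_e(h) + n ].
    """
    if not 0.0 <= h < 1.0:
        raise ValueError(f"h must lie in [0, 1), got {h}")
    y_rot = np.asarray(y_rot, dtype=float)
    n = y_rot.size
    lam = h / (1.0 - h)
    v = lam * np.asarray(eigvals, dtype=float) + 1.0
    s2e = float(np.mean(y_rot**2 / v))
    if s2e <= 0.0:
        return -np.inf
    return -0.5 * (float(np.sum(np.log(v))) + n * np.log(s2e) + n)


def _reml_reduce(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project out the intercept: work in the (n-1)-dim complement of 1."""
    n = y.size
    # Householder-free orthonormal basis of 1-perp via Helmert contrasts
    K = np.zeros((n, n - 1))
    for i in range(1, n):
        K[:i, i - 1] = 1.0
        K[i, i - 1] = -float(i)
        K[:, i - 1] /= np.sqrt(i * (i + 1.0))
    return K.T @ y, K.T @ G @ K


def fit_ml(
    y: np.ndarray,
    G: GRM | np.ndarray,
    reml: bool = False,
    grid_points: int = 101,
    tol: float = 1e-8,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarCompFit:
    """Maximise the likelihood over ``h`` in ``[0, 1 - 1e-6]``.

    A coarse grid locates the basin; bounded Brent refinement polishes the
    optimum to ``tol`` in ``h``; the estimates back-transform as
    ``sigma2_e = mean(y*^2/v)`` and ``sigma2_u = lambda * sigma2_e``.
    ``boundary`` flags estimates within grid resolution of 0 or the upper
    cap; ``identifiable`` is False when the profile is flat (e.g. G = I,
    where only the total variance is identifiable).  A precomputed
    eigendecomposition may be supplied via ``eig`` (ML mode only) to avoid
    repeating the O(n^3) step across fits that share a GRM.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes contain non-finite values")
    M = _as_matrix(G)
    if y.size != M.shape[0]:
        raise ValueError("length(y) must equal dim(G)")

    if reml:
        y_red, M_red = _reml_reduce(y, M)
        U, d = eigendecompose(M_red)
        y_rot = U.T @ y_red
    else:
        if eig is not None:
            U, d = eig
        else:
            U, d = eigendecompose(M)
        y_rot = U.T @ y

    n = y_rot.size
    grid = np.linspace(0.0, _H_MAX, grid_points)
    ll_grid = np.array([profile_loglik(y_rot, d, h) for h in grid])
    k = int(np.argmax(ll_grid))
    identifiable = bool(ll_grid.max() - ll_grid.min() > 1e-8 * max(1.0, abs(ll_grid.max())))

    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_points - 1)]
    if identifiable and hi > lo:
        res = minimize_scalar(
            lambda h: -profile_loglik(y_rot, d, h),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        h_hat = float(res.x)
        ll_hat = -float(res.fun)
        if ll_grid[k] > ll_hat:  # refinement never worsens the grid optimum
            h_hat, ll_hat = float(grid[k]), float(ll_grid[k])
    else:
        h_hat, ll_hat = float(grid[k]), float(ll_grid[k])

    lam = h_hat / (1.0 - h_hat)
    v = lam * d + 1.0
    s2e = float(np.mean(y_rot**2 / v))
    s2u = lam * s2e
    grid_step = grid[1] - grid[0]
    boundary = h_hat <= grid_step or h_hat >= _H_MAX - grid_step
    return VarCompFit(
        sigma2_u_hat=s2u,
        sigma2_e_hat=s2e,
        h2_u_hat=h_hat,
        loglik=ll_hat,
        n_obs=n,
        boundary=bool(boundary),
        identifiable=identifiable,
        optimizer_trace={"grid_points": grid_points, "grid_argmax": k, "reml": reml},
    )
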