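"""Fixed population parameters of the structural QTL model and its marker
projection.

Notation (all quantities are parameters of a conceptual population, never
sample estimates; covariances therefore use divisor ``n``):

* ``z`` — centered QTL dosages, ``x`` — centered marker dosages.
* ``alpha = Sigma_z^{-1} Cov(z, g)`` — allele-substitution effects, the
  population regression of genetic value on QTL allele content.
* ``sigma2_a = alpha' Sigma_z alpha`` — additive variance, LD cross-terms
  included.
* ``beta = Sigma_x^{-1} Sigma_xz alpha`` — marker effects, i.e. the
  projection of QTL effects onto the marker span (linear combinations of
  QTL effects, not free parameters).
* ``sigma2_g = beta' Sigma_x beta = alpha' Sigma_zx Sigma_x^{-1} Sigma_xz
  alpha`` — genomic variance, the slice of additive variance a linear
  regression on the markers can capture.
* ``h2_g = h2 * sigma2_g / sigma2_a`` — genomic heritability; the gap
  ``(sigma2_a - sigma2_g)/sigma2_a`` is the missing-heritability fraction.

The contrastive "statistical" variance of random-effects marker models
(``sigma2_u = sigma2_b * sum_j 2 pi_j (1-pi_j)``) is provided only to show
how it ignores LD; it is never used as the population parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from genoherit.synthetic_genomes import GenomePopulation
from genoherit.trait_sim import TraitArchitecture

__all__ = [
    "PopulationParams",
    "SingularCovarianceError",
    "covariance_blocks",
    "additive_effects",
    "additive_variance",
    "marker_effects",
    "genomic_variance",
    "variance_decomposition",
    "genomic_heritability",
    "independent_pairs_variance",
    "sample_genomic_variance",
    "naive_statistical_variance",
    "population_params",
    "blocked_variance_decomposition",
]

#: Condition number beyond which Sigma_x / Sigma_z are treated as singular.
CONDITION_LIMIT = 1e12

#: Loci cap for dense (non-blocked) parameter computation.
DENSE_LOCUS_CAP = 5000


class SingularCovarianceError(np.linalg.LinAlgError):
    """Raised when a covariance matrix is numerically singular.

    Carries the indices of offending (collinear / duplicate) columns when
    they can be identified.
    """

    def __init__(self, msg: str, offending: Sequence[int] | None = None):
        super().__init__(msg)
        self.offending = list(offending) if offending is not None else []


@dataclass
class PopulationParams:
    """The full set of fixed population quantities for one marker panel."""

    sigma_z: np.ndarray
    sigma_x: np.ndarray
    sigma_xz: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    sigma2_a: float
    sigma2_g: float
    sigma2_gbar: float
    sigma2_y: float
    h2: float
    h2_g: float

    @property
    def missing_fraction(self) -> float:
        return self.sigma2_gbar / self.sigma2_a


def _center(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    return mat - mat.mean(axis=0)


def _pop_cov(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Method-of-moments cross-covariance with divisor n (population)."""
    return _center(a).T @ _center(b) / a.shape[0]


def _symmetrize(m: np.ndarray) -> np.ndarray:
    return (m + m.T) / 2.0


def _solve_spd(sigma: np.ndarray, rhs: np.ndarray, name: str, allow_pinv: bool = False) -> np.ndarray:
    """Solve ``sigma @ out = rhs`` failing loudly on collinearity.

    Collinearity is detected by a condition-number threshold; the error
    names the columns most likely involved (pairs with |correlation| ~ 1).
    With ``allow_pinv`` a Moore–Penrose fallback is used instead (results
    then depend on the generalized-inverse convention).
    """
    sigma = _symmetrize(np.atleast_2d(np.asarray(sigma, dtype=float)))
    if sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"{name} must be square")
    cond = np.linalg.cond(sigma)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        if allow_pinv:
            return np.linalg.pinv(sigma, hermitian=True) @ rhs
        d = np.sqrt(np.clip(np.diag(sigma), 1e-300, None))
        corr = sigma / np.outer(d, d)
        np.fill_diagonal(corr, 0.0)
        bad = sorted(set(np.flatnonzero(np.any(np.abs(corr) > 1 - 1e-9, axis=1)).tolist()))
        raise SingularCovarianceError(
            f"{name} is numerically singular (cond={cond:.3g}); "
            f"collinear/duplicate columns: {bad or 'undetermined'}",
            offending=bad,
        )
    return np.linalg.solve(sigma, rhs)


def covariance_blocks(
    pop: GenomePopulation,
    qtl_idx: np.ndarray | None = None,
    marker_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population covariance matrices (Sigma_z, Sigma_x, Sigma_xz).

    Defaults take QTL from the ``is_qtl`` flags and markers as every
    non-QTL locus; pass explicit index arrays to use a different panel
    (panels may include QTL columns).  Divisor is ``n`` throughout.
    """
    if pop.n_individuals < 2:
        raise ValueError("population must contain at least 2 individuals")
    if qtl_idx is None:
        qtl_idx = pop.qtl_indices
    if marker_idx is None:
        marker_idx = np.flatnonzero(~pop.is_qtl)
    qtl_idx = np.asarray(qtl_idx, dtype=np.int64)
    marker_idx = np.asarray(marker_idx, dtype=np.int64)
    if qtl_idx.size == 0 or marker_idx.size == 0:
        raise ValueError("empty QTL or marker partition")
    z = _center(pop.dosages[:, qtl_idx])
    x = _center(pop.dosages[:, marker_idx])
    n = pop.n_individuals
    sigma_z = _symmetrize(z.T @ z / n)
    sigma_x = _symmetrize(x.T @ x / n)
    sigma_xz = x.T @ z / n
    return sigma_z, sigma_x, sigma_xz


def additive_effects(sigma_z: np.ndarray, sigma_zg: np.ndarray, allow_pinv: bool = False) -> np.ndarray:
    """Allele-substitution effects ``alpha = Sigma_z^{-1} Cov(z, g)``."""
    sigma_zg = np.atleast_1d(np.asarray(sigma_zg, dtype=float))
    return _solve_spd(sigma_z, sigma_zg, "sigma_z", allow_pinv)


def additive_variance(alpha: np.ndarray, sigma_z: np.ndarray) -> float:
    """Additive genetic variance ``alpha' Sigma_z alpha`` (LD terms included)."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    sigma_z = np.atleast_2d(np.asarray(sigma_z, dtype=float))
    return float(alpha @ sigma_z @ alpha)


def marker_effects(
    sigma_x: np.ndarray,
    sigma_xz: np.ndarray,
    alpha: np.ndarray,
    allow_pinv: bool = False,
) -> np.ndarray:
    """Marker effects ``beta = Sigma_x^{-1} Sigma_xz alpha``."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    sigma_xz = np.atleast_2d(np.asarray(sigma_xz, dtype=float))
    if sigma_xz.shape[1] != alpha.size:
        # 1-D row given for a single-QTL system
        sigma_xz = sigma_xz.reshape(-1, alpha.size)
    return _solve_spd(sigma_x, sigma_xz @ alpha, "sigma_x", allow_pinv)


def genomic_variance(
    alpha: np.ndarray,
    sigma_zx: np.ndarray,
    sigma_x: np.ndarray,
    allow_pinv: bool = False,
) -> float:
    """Genomic variance ``alpha' Sigma_zx Sigma_x^{-1} Sigma_xz alpha``.

    Equal to ``beta' Sigma_x beta``; depends on marker LD through
    ``Sigma_x^{-1}`` and can exceed the LD-ignoring per-locus sum
    ``sum_j Var(x_j) beta_j^2``.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    sigma_zx = np.atleast_2d(np.asarray(sigma_zx, dtype=float))
    if sigma_zx.shape[0] != alpha.size:
        sigma_zx = sigma_zx.reshape(alpha.size, -1)
    v = sigma_zx.T @ alpha  # Sigma_xz alpha
    return float(v @ _solve_spd(sigma_x, v, "sigma_x", allow_pinv))


def variance_decomposition(
    alpha: np.ndarray,
    sigma_z: np.ndarray,
    sigma_zx: np.ndarray,
    sigma_x: np.ndarray,
    allow_pinv: bool = False,
) -> tuple[float, float, float]:
    """(sigma2_a, sigma2_g, sigma2_gbar) with sigma2_a = sigma2_g + sigma2_gbar.

    The missing variance is the quadratic form of the Schur complement
    ``Sigma_z - Sigma_zx Sigma_x^{-1} Sigma_xz`` and is therefore
    non-negative; a negative value beyond numerical tolerance raises.
    """
    s2a = additive_variance(alpha, sigma_z)
    s2g = genomic_variance(alpha, sigma_zx, sigma_x, allow_pinv)
    s2gbar = s2a - s2g
    tol = 1e-8 * max(1.0, abs(s2a))
    if s2gbar < -tol:
        raise ValueError(
            f"internal inconsistency: sigma2_gbar={s2gbar:.3g} < 0 "
            "(Schur complement must be PSD)"
        )
    return s2a, s2g, max(s2gbar, 0.0)


def genomic_heritability(sigma2_g: float, sigma2_a: float, h2: float) -> tuple[float, float]:
    """(h2_g, missing_fraction) from the variance ratio.

    ``h2_g = h2 * sigma2_g / sigma2_a``; the missing fraction
    ``(sigma2_a - sigma2_g) / sigma2_a`` equals ``(h2 - h2_g)/h2``.
    """
    if sigma2_a <= 0:
        raise ValueError("undefined heritability: sigma2_a must be positive")
    ratio = sigma2_g / sigma2_a
    return h2 * ratio, 1.0 - ratio


def independent_pairs_variance(pair_params: Sequence[tuple[float, float, float]]) -> float:
    """Genomic variance for mutually-LE marker–QTL pairs.

    Each entry is ``(Var(z_j), r_j^2, alpha_j)`` for the j-th pair; the
    contributions ``Var(z_j) * r_j^2 * alpha_j^2`` add because all
    cross-pair covariances vanish.  Callers are responsible for the pairs
    actually being in mutual linkage equilibrium.
    """
    return float(sum(vz * r2 * a * a for vz, r2, a in pair_params))


def sample_genomic_variance(X: np.ndarray, beta: np.ndarray) -> float:
    """Plug-in sample analogue ``beta' (X'X/n) beta`` of the genomic variance.

    ``X`` must be column-centered; this replaces Sigma_x by its
    method-of-moments estimator and accounts for multi-locus LD, unlike
    the IID-effects variance of random-effects marker models.
    """
    X = np.asarray(X, dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    v = X @ beta
    return float(v @ v / X.shape[0])


def naive_statistical_variance(
    marker_freqs: Sequence[float] | np.ndarray | None,
    sigma2_b: float,
    standardized: bool = False,
    p: int | None = None,
) -> float:
    """IID-effects "genomic variance" of random-effects marker models.

    ``sigma2_b * sum_j 2 pi_j (1 - pi_j)`` for raw dosages under HW, or
    ``p * sigma2_b`` when genotypes are standardized.  Provided only for
    contrast with :func:`genomic_variance`: it ignores LD entirely.
    """
    if sigma2_b < 0:
        raise ValueError("sigma2_b must be non-negative")
    if standardized:
        if p is None:
            if marker_freqs is None:
                raise ValueError("need p (or marker_freqs) when standardized")
            p = len(np.atleast_1d(marker_freqs))
        return float(p * sigma2_b)
    freqs = np.atleast_1d(np.asarray(marker_freqs, dtype=float))
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("marker frequencies must lie in (0, 1)")
    return float(sigma2_b * np.sum(2.0 * freqs * (1.0 - freqs)))


# ---------------------------------------------------------------------------
# whole-population drivers


def population_params(
    pop: GenomePopulation,
    arch: TraitArchitecture,
    marker_idx: np.ndarray | None = None,
    allow_pinv: bool = False,
    locus_cap: int = DENSE_LOCUS_CAP,
) -> PopulationParams:
    """Dense computation of every population parameter for one marker panel.

    Intended for panels of up to ``locus_cap`` loci; blocked genomes with
    many more loci should use :func:`blocked_variance_decomposition`,
    which exploits between-block independence instead of inverting a dense
    Sigma_x.
    """
    if marker_idx is None:
        marker_idx = np.flatnonzero(~pop.is_qtl)
    marker_idx = np.asarray(marker_idx, dtype=np.int64)
    if marker_idx.size > locus_cap:
        raise ValueError(
            f"dense parameter computation capped at {locus_cap} loci "
            f"(got {marker_idx.size}); use blocked_variance_decomposition"
        )
    sigma_z, sigma_x, sigma_xz = covariance_blocks(pop, arch.qtl_idx, marker_idx)
    alpha = np.asarray(arch.alpha, dtype=float)
    beta = marker_effects(sigma_x, sigma_xz, alpha, allow_pinv)
    s2a, s2g, s2gbar = variance_decomposition(alpha, sigma_z, sigma_xz.T, sigma_x, allow_pinv)
    sigma2_y = s2a + arch.sigma2_delta
    h2 = s2a / sigma2_y
    h2_g, _ = genomic_heritability(s2g, s2a, h2)
    return PopulationParams(
        sigma_z=sigma_z,
        sigma_x=sigma_x,
        sigma_xz=sigma_xz,
        alpha=alpha,
        beta=beta,
        sigma2_a=s2a,
        sigma2_g=s2g,
        sigma2_gbar=s2gbar,
        sigma2_y=sigma2_y,
        h2=h2,
        h2_g=h2_g,
    )


def blocked_variance_decomposition(
    pop: GenomePopulation,
    arch: TraitArchitecture,
    marker_idx: np.ndarray,
) -> tuple[float, float, float]:
    """(sigma2_a, sigma2_g, sigma2_gbar) exploiting block independence.

    Loci in different blocks are in linkage equilibrium by construction, so
    Sigma_x is block-diagonal and the quadratic forms decompose as sums of
    per-block contributions; only blocks containing at least one QTL can
    contribute to sigma2_g.  Within a block the realized covariances
    (divisor n) are used exactly; monomorphic marker columns are dropped
    from the panel (their covariances are identically zero).
    """
    marker_idx = np.asarray(marker_idx, dtype=np.int64)
    alpha = np.asarray(arch.alpha, dtype=float)
    qtl_idx = np.asarray(arch.qtl_idx, dtype=np.int64)
    n = pop.n_individuals

    s2a = 0.0
    s2g = 0.0
    qtl_blocks = pop.block_of_locus[qtl_idx]
    # only markers sharing a block with a QTL can contribute to sigma2_g
    in_scope = np.isin(pop.block_of_locus[marker_idx], qtl_blocks) if marker_idx.size else np.empty(0, bool)
    marker_idx = marker_idx[in_scope]
    marker_blocks = pop.block_of_locus[marker_idx]
    for blk in np.unique(qtl_blocks):
        sel = qtl_blocks == blk
        q_in = qtl_idx[sel]
        a_in = alpha[sel]
        z = _center(pop.dosages[:, q_in])
        sigma_z = z.T @ z / n
        s2a += float(a_in @ sigma_z @ a_in)
        m_in = marker_idx[marker_blocks == blk]
        if m_in.size == 0:
            continue
        x = _center(pop.dosages[:, m_in])
        # drop monomorphic markers (zero covariance with everything)
        poly = x.std(axis=0) > 0
        if not poly.all():
            x = x[:, poly]
            if x.shape[1] == 0:
                continue
        sigma_x = _symmetrize(x.T @ x / n)
        v = (x.T @ z / n) @ a_in  # Sigma_xz alpha, this block
        try:
            s2g += float(v @ _solve_spd(sigma_x, v, f"sigma_x[block {blk}]"))
        except SingularCovarianceError:
            # within-block collinearity (e.g. copy_prob == 1): least-norm inverse
            s2g += float(v @ (np.linalg.pinv(sigma_x, hermitian=True) @ v))
    s2gbar = max(s2a - s2g, 0.0)
    return s2a, s2g, s2gbar
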