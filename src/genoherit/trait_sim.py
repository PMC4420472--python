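"""Additive trait architectures and phenotype generation.

The data-generating model is the structural QTL model
``y_i = alpha' z_i + delta_i`` with fixed allele-substitution effects
``alpha`` and iid Gaussian residuals.  Residual variance is calibrated
against the *realized* additive variance of the simulated population, so
the trait heritability equals its target exactly in every population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from genoherit.synthetic_genomes import GenomePopulation

__all__ = [
    "TraitArchitecture",
    "PhenotypeSet",
    "sample_effects",
    "calibrate_residual_variance",
    "simulate_phenotypes",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
]


@dataclass
class TraitArchitecture:
    """QTL index set, substitution effects and residual variance.

    ``alpha`` is in trait units per copy of the "1" allele; ``sigma2_delta``
    is the variance of the non-genetic residual; ``target_h2`` the intended
    ratio of additive to phenotypic variance.
    """

    qtl_idx: np.ndarray
    alpha: np.ndarray
    sigma2_delta: float = np.nan
    target_h2: float = 0.5

    def __post_init__(self) -> None:
        self.qtl_idx = np.asarray(self.qtl_idx, dtype=np.int64)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != self.qtl_idx.shape:
            raise ValueError("alpha must have one entry per QTL")
        if not 0.0 < self.target_h2 < 1.0:
            raise ValueError("target_h2 must lie in (0, 1)")
        if np.isfinite(self.sigma2_delta) and self.sigma2_delta < 0:
            raise ValueError("sigma2_delta must be non-negative")


@dataclass
class PhenotypeSet:
    y: np.ndarray  # centered phenotypes
    g: np.ndarray  # true additive genetic values alpha' z (centered)
    realized_h2: float


def sample_effects(n_qtl: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """IID standard-normal substitution effects (scale set later by calibration)."""
    if n_qtl < 1:
        raise ValueError("need at least one QTL")
    return np.random.default_rng(rng).standard_normal(n_qtl)


def _genetic_values(pop: GenomePopulation, arch: TraitArchitecture) -> np.ndarray:
    z = pop.dosages[:, arch.qtl_idx].astype(float)
    z -= z.mean(axis=0)
    return z @ arch.alpha


def calibrate_residual_variance(pop: GenomePopulation, arch: TraitArchitecture) -> float:
    """Residual variance that makes the population heritability exact.

    With sigma2_a = Var(alpha' z) over the full population (divisor n),
    returns ``sigma2_a * (1 - h2) / h2`` so that
    ``sigma2_a / (sigma2_a + sigma2_delta) == target_h2``.
    """
    g = _genetic_values(pop, arch)
    sigma2_a = float(g.var())  # population divisor n
    if sigma2_a <= 0.0:
        raise ValueError("degenerate trait: all QTL monomorphic (sigma2_a = 0)")
    h2 = arch.target_h2
    return sigma2_a * (1.0 - h2) / h2


def simulate_phenotypes(
    pop: GenomePopulation,
    arch: TraitArchitecture,
    rng: np.random.Generator | int | None = None,
) -> PhenotypeSet:
    """Generate ``y = g + delta`` for the whole population and re-center.

    Centering uses the full-population mean, before any subsampling; the
    realized heritability Var(g)/Var(y) is recorded alongside.
    """
    if not np.isfinite(arch.sigma2_delta):
        raise ValueError("sigma2_delta is not set; run calibrate_residual_variance first")
    rng = np.random.default_rng(rng)
    g = _genetic_values(pop, arch)
    delta = rng.normal(0.0, np.sqrt(arch.sigma2_delta), size=pop.n_individuals)
    y = g + delta
    y -= y.mean()
    var_y = y.var()
    realized = float(g.var() / var_y) if var_y > 0 else 0.0
    return PhenotypeSet(y=y, g=g, realized_h2=realized)


def make_architecture(
    pop: GenomePopulation,
    target_h2: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> TraitArchitecture:
    """Sample effects for the population's QTL and calibrate the residual."""
    qtl = pop.qtl_indices
    arch = TraitArchitecture(
        qtl_idx=qtl,
        alpha=sample_effects(qtl.size, rng),
        target_h2=target_h2,
    )
    return replace(arch, sigma2_delta=calibrate_residual_variance(pop, arch))


def write_phenotypes_tsv(phen: PhenotypeSet, path: str | Path, with_genetic_values: bool = False) -> None:
    data = {"individual": [f"ind{i}" for i in range(phen.y.size)], "phenotype": phen.y}
    if with_genetic_values:
        data["genetic_value"] = phen.g
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if "phenotype" not in df.columns:
        raise ValueError("phenotype table needs a 'phenotype' column")
    return df["phenotype"].to_numpy(dtype=float)
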