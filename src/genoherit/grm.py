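"""Genomic-relationship matrices (GRMs) from designated locus subsets.

Two scaling conventions are provided:

* ``standardized_avg`` — columns centered and scaled to unit sample
  variance, ``G = W W' / k`` with ``k`` the number of loci used; the mean
  diagonal is ~1 and the implied per-marker prior variance of a
  random-effects model is ``sigma2_u / k``.
* ``vanraden`` — columns centered only, ``G = W W' / sum_j 2 p_j (1-p_j)``
  with ``p_j`` the sample allele frequency (VanRaden 2008).

Centering/scaling statistics are computed on the matrix handed in (the
estimation sample), because that is all an analyst would ever see.
Monomorphic-in-sample loci are dropped from the subset (and from ``k``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from genoherit.synthetic_genomes import GenomePopulation

__all__ = ["GRM", "build_grm", "write_grm", "read_grm"]

Scaling = Literal["standardized_avg", "vanraden"]


@dataclass
class GRM:
    """Symmetric PSD relationship matrix plus its provenance."""

    matrix: np.ndarray
    locus_subset: str
    scaling: str
    n_loci_used: int
    n_dropped_monomorphic: int = 0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _resolve_subset(
    dosages: np.ndarray,
    pop: GenomePopulation | None,
    subset: str | Sequence[int] | np.ndarray,
) -> tuple[np.ndarray, str]:
    if isinstance(subset, str):
        if pop is None:
            raise ValueError("named subsets require a GenomePopulation")
        parts = [p.strip() for p in subset.split("+")]
        if parts == ["ALL"]:
            idx = np.arange(pop.n_loci)
        else:
            masks = []
            for p in parts:
                if p not in ("QTL", "MRK.LD", "MRK.LE"):
                    raise ValueError(f"unknown locus class {p!r}")
                masks.append(pop.ld_class == p)
            idx = np.flatnonzero(np.logical_or.reduce(masks))
        return idx, subset
    idx = np.asarray(subset, dtype=np.int64)
    return idx, "custom"


def build_grm(
    dosages: np.ndarray | GenomePopulation,
    subset: str | Sequence[int] | np.ndarray = "ALL",
    scaling: Scaling = "standardized_avg",
    pop: GenomePopulation | None = None,
) -> GRM:
    """Build a GRM from a dosage matrix (individuals x loci).

    ``dosages`` may be a plain matrix (with ``subset`` as explicit column
    indices) or a :class:`GenomePopulation`, in which case ``subset`` may
    also be a class label — ``"QTL"``, ``"MRK.LD"``, ``"MRK.LE"``,
    ``"ALL"`` or a ``+``-combination such as ``"QTL+MRK.LD"``.
    """
    if isinstance(dosages, GenomePopulation):
        pop = dosages
        dosages = pop.dosages
    idx, label = _resolve_subset(dosages, pop, subset)
    if idx.size == 0:
        raise ValueError(f"locus subset {label!r} is empty")
    X = np.asarray(dosages, dtype=float)[:, idx]

    freqs = X.mean(axis=0) / 2.0
    W = X - 2.0 * freqs
    sd = W.std(axis=0)
    poly = sd > 0.0
    n_dropped = int(np.count_nonzero(~poly))
    if not poly.any():
        raise ValueError(f"all loci in subset {label!r} are monomorphic in-sample")
    W = W[:, poly]
    k = W.shape[1]

    if scaling == "standardized_avg":
        W = W / sd[poly]
        G = W @ W.T / k
    elif scaling == "vanraden":
        p = freqs[poly]
        denom = float(np.sum(2.0 * p * (1.0 - p)))
        G = W @ W.T / denom
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    G = (G + G.T) / 2.0
    return GRM(matrix=G, locus_subset=label, scaling=scaling, n_loci_used=k, n_dropped_monomorphic=n_dropped)


def write_grm(grm: GRM, path: str | Path) -> None:
    """Matrix as TSV plus a JSON sidecar with subset/scaling/k."""
    path = Path(path)
    pd.DataFrame(grm.matrix).to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")
    sidecar = {
        "locus_subset": grm.locus_subset,
        "scaling": grm.scaling,
        "n_loci_used": grm.n_loci_used,
        "n_dropped_monomorphic": grm.n_dropped_monomorphic,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_grm(path: str | Path) -> GRM:
    path = Path(path)
    mat = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return GRM(
        matrix=(mat + mat.T) / 2.0,
        locus_subset=meta.get("locus_subset", "unknown"),
        scaling=meta.get("scaling", "unknown"),
        n_loci_used=meta.get("n_loci_used", mat.shape[0]),
        n_dropped_monomorphic=meta.get("n_dropped_monomorphic", 0),
    )
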