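"""Blocked-LD genotype simulator.

Populations are built from mutually independent LD blocks.  Within a block,
haplotypes follow a stationary two-state "copy/refresh" Markov chain: the
allele at locus ``j+1`` copies the allele at locus ``j`` with probability
``c`` (the copy probability) and is otherwise a fresh Bernoulli draw at the
block's allele frequency ``theta``.  The chain is stationary, so every locus
in a block has marginal allele frequency ``theta``, and the correlation
between alleles ``k`` loci apart is ``c**k`` — LD decays geometrically with
distance and is tuned by a single knob.

Haplotypes are paired at random into diploids (dosage = sum of the two
haploid alleles), and blocks are concatenated into a genome.  Because blocks
never exchange information, loci in different blocks are in linkage
equilibrium by construction.

Two transition designs are supported: a fixed copy probability shared by
all blocks (homogeneous LD), or a per-block copy probability drawn from a
Beta distribution (heterogeneous LD, as one sees across a real genome).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlockSpec",
    "GenomePopulation",
    "sample_haplotype_block",
    "simulate_population",
    "assign_qtl",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_annotation_tsv",
    "read_annotation_tsv",
    "write_vcf",
    "read_vcf_dosages",
]

#: Locus classes: causal loci, markers sharing a block with a causal locus,
#: and markers in blocks with no causal locus (linkage equilibrium with QTL).
LD_CLASSES = ("QTL", "MRK.LD", "MRK.LE")


@dataclass(frozen=True)
class BlockSpec:
    """Design of a blocked genome.

    Parameters
    ----------
    n_blocks, loci_per_block
        Number of independent LD blocks and loci per block; the genome has
        ``n_blocks * loci_per_block`` loci.
    transition_mode
        ``"fixed"``: every block uses ``copy_prob``.  ``"random"``: each
        block draws its copy probability from ``Beta(*copy_prob_hyper)``.
    copy_prob
        Probability that a locus copies the allele of its left neighbour
        within a haplotype (fixed mode).
    copy_prob_hyper
        Beta shape parameters for the per-block copy probability (random
        mode).
    init_freq_range
        Each block's stationary allele frequency is drawn uniformly from
        this closed sub-interval of (0, 1).
    """

    n_blocks: int
    loci_per_block: int
    transition_mode: Literal["fixed", "random"] = "fixed"
    copy_prob: float = 0.8
    copy_prob_hyper: tuple[float, float] = (8.0, 2.0)
    init_freq_range: tuple[float, float] = (0.1, 0.5)

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.loci_per_block < 1:
            raise ValueError("n_blocks and loci_per_block must be positive")
        if self.transition_mode not in ("fixed", "random"):
            raise ValueError(f"unknown transition_mode {self.transition_mode!r}")
        if not 0.0 <= self.copy_prob <= 1.0:
            raise ValueError("copy_prob must lie in [0, 1]")
        a, b = self.copy_prob_hyper
        if a <= 0 or b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        lo, hi = self.init_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("init_freq_range must be a sub-interval of (0, 1)")

    @property
    def n_loci(self) -> int:
        return self.n_blocks * self.loci_per_block


@dataclass
class GenomePopulation:
    """A diploid population with per-locus annotations.

    ``dosages`` counts copies of the "1" allele (0/1/2, stored as int8 and
    never centred here — centring is an estimation-time choice).
    """

    dosages: np.ndarray  # (n_individuals, n_loci) int8 in {0,1,2}
    block_of_locus: np.ndarray  # (n_loci,) int
    is_qtl: np.ndarray  # (n_loci,) bool
    ld_class: np.ndarray  # (n_loci,) object/str in LD_CLASSES
    seed: int | None = None
    block_freqs: np.ndarray | None = None
    block_copy_probs: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    def class_indices(self, ld_class: str) -> np.ndarray:
        """Locus indices belonging to one of ``LD_CLASSES``."""
        if ld_class not in LD_CLASSES:
            raise ValueError(f"unknown ld_class {ld_class!r}")
        return np.flatnonzero(self.ld_class == ld_class)

    def monomorphic_loci(self) -> np.ndarray:
        """Loci whose realized dosage is constant across individuals."""
        return np.flatnonzero(np.all(self.dosages == self.dosages[0], axis=0))


def _validate_chain_params(block_freq: float, copy_prob: float) -> None:
    if not 0.0 < block_freq < 1.0:
        raise ValueError(f"block_freq must lie in (0, 1), got {block_freq}")
    if not 0.0 <= copy_prob <= 1.0:
        raise ValueError(f"copy_prob must lie in [0, 1], got {copy_prob}")


def sample_haplotype_block(
    spec: BlockSpec,
    block_freq: float,
    copy_prob: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw haplotypes of length ``spec.loci_per_block`` from the block chain.

    The first locus is Bernoulli(``block_freq``); each subsequent locus
    copies its left neighbour with probability ``copy_prob`` and otherwise
    redraws Bernoulli(``block_freq``).  Returns a ``(size, loci_per_block)``
    int8 array (a 1-D array when ``size == 1``).
    """
    _validate_chain_params(block_freq, copy_prob)
    L = spec.loci_per_block
    hap = np.empty((size, L), dtype=np.int8)
    # One uniform u per transition serves both decisions: copy when
    # u < c; otherwise (u - c)/(1 - c) is again U(0,1), so the fresh
    # draw is (u - c)/(1 - c) < theta, i.e. u < c + (1 - c) * theta.
    u = rng.random((size, L))
    hap[:, 0] = u[:, 0] < block_freq
    c = copy_prob
    thresh = c + (1.0 - c) * block_freq
    for j in range(1, L):
        uj = u[:, j]
        hap[:, j] = np.where(uj < c, hap[:, j - 1], uj < thresh)
    return hap[0] if size == 1 else hap


def simulate_population(
    spec: BlockSpec,
    n_individuals: int,
    rng: np.random.Generator | int | np.random.SeedSequence,
) -> GenomePopulation:
    """Simulate a diploid population under the blocked-LD design.

    Per block (independently, on its own RNG substream so that changing the
    block count does not perturb other blocks): draw the block allele
    frequency and copy probability, generate ``2 * n_individuals``
    haplotypes, and pair them by a random permutation into diploid dosages.
    Deterministic given the seed.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    seed_record: int | None = None
    if isinstance(rng, (int, np.integer)):
        seed_record = int(rng)
        ss = np.random.SeedSequence(seed_record)
    elif isinstance(rng, np.random.SeedSequence):
        ss = rng
    else:
        # Derive a child seed sequence from the caller's generator so the
        # per-block substream contract still holds.
        ss = np.random.SeedSequence(rng.integers(0, 2**63 - 1))

    children = ss.spawn(spec.n_blocks)
    # Fortran order: per-block column writes are contiguous; downstream
    # consumers only ever slice columns.
    dosages = np.empty((n_individuals, spec.n_loci), dtype=np.int8, order="F")
    block_of_locus = np.repeat(np.arange(spec.n_blocks), spec.loci_per_block)
    freqs = np.empty(spec.n_blocks)
    cprobs = np.empty(spec.n_blocks)
    lo, hi = spec.init_freq_range
    a, b = spec.copy_prob_hyper
    for blk, child in enumerate(children):
        brng = np.random.default_rng(child)
        theta = brng.uniform(lo, hi)
        c = spec.copy_prob if spec.transition_mode == "fixed" else brng.beta(a, b)
        freqs[blk] = theta
        cprobs[blk] = c
        haps = sample_haplotype_block(spec, theta, c, brng, size=2 * n_individuals)
        perm = brng.permutation(2 * n_individuals)
        sl = slice(blk * spec.loci_per_block, (blk + 1) * spec.loci_per_block)
        np.add(
            haps[perm[:n_individuals]],
            haps[perm[n_individuals:]],
            out=dosages[:, sl],
        )

    n_loci = spec.n_loci
    return GenomePopulation(
        dosages=dosages,
        block_of_locus=block_of_locus,
        is_qtl=np.zeros(n_loci, dtype=bool),
        ld_class=np.full(n_loci, "MRK.LE", dtype=object),
        seed=seed_record,
        block_freqs=freqs,
        block_copy_probs=cprobs,
    )


def _recompute_ld_class(pop: GenomePopulation) -> np.ndarray:
    """QTL / MRK.LD (shares a block with a QTL) / MRK.LE (no QTL in block)."""
    qtl_blocks = np.unique(pop.block_of_locus[pop.is_qtl])
    in_qtl_block = np.isin(pop.block_of_locus, qtl_blocks)
    cls = np.full(pop.n_loci, "MRK.LE", dtype=object)
    cls[in_qtl_block] = "MRK.LD"
    cls[pop.is_qtl] = "QTL"
    return cls


def assign_qtl(
    pop: GenomePopulation,
    n_qtl: int,
    mode: Literal["block_random", "genome_random"] = "block_random",
    rng: np.random.Generator | int | None = None,
) -> GenomePopulation:
    """Flag ``n_qtl`` loci as causal and reclassify the rest.

    ``block_random`` picks ``n_qtl`` distinct blocks and one locus within
    each (no block carries two QTL — the short-block design); in
    ``genome_random`` positions are uniform over the whole genome (long
    blocks may then carry several QTL).  Returns a new population sharing
    the dosage matrix.
    """
    rng = np.random.default_rng(rng)
    blocks = np.unique(pop.block_of_locus)
    if mode == "block_random":
        if n_qtl > blocks.size:
            raise ValueError(f"n_qtl={n_qtl} exceeds the {blocks.size} blocks")
        chosen_blocks = rng.choice(blocks, size=n_qtl, replace=False)
        qtl_idx = np.empty(n_qtl, dtype=np.int64)
        for k, blk in enumerate(chosen_blocks):
            in_block = np.flatnonzero(pop.block_of_locus == blk)
            qtl_idx[k] = rng.choice(in_block)
    elif mode == "genome_random":
        if n_qtl > pop.n_loci:
            raise ValueError(f"n_qtl={n_qtl} exceeds the {pop.n_loci} loci")
        qtl_idx = rng.choice(pop.n_loci, size=n_qtl, replace=False)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    is_qtl = np.zeros(pop.n_loci, dtype=bool)
    is_qtl[qtl_idx] = True
    out = replace(pop, is_qtl=is_qtl)
    out.ld_class = _recompute_ld_class(out)
    return out


# ---------------------------------------------------------------------------
# readers / writers


def _locus_ids(n_loci: int) -> list[str]:
    return [f"L{j}" for j in range(n_loci)]


def write_dosage_tsv(pop: GenomePopulation, path: str | Path) -> None:
    """Individuals x loci integer dosage matrix, header row of locus ids."""
    df = pd.DataFrame(
        pop.dosages,
        index=[f"ind{i}" for i in range(pop.n_individuals)],
        columns=_locus_ids(pop.n_loci),
    )
    df.to_csv(path, sep="\t", index_label="individual")


def read_dosage_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy()
    if not np.isin(np.unique(mat), [0, 1, 2]).all():
        raise ValueError("dosage matrix entries must be 0, 1 or 2")
    return mat.astype(np.int8)


def write_annotation_tsv(pop: GenomePopulation, path: str | Path) -> None:
    pd.DataFrame(
        {
            "locus": _locus_ids(pop.n_loci),
            "block": pop.block_of_locus,
            "is_qtl": pop.is_qtl.astype(int),
            "ld_class": pop.ld_class,
        }
    ).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"locus", "block", "is_qtl", "ld_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    return df


def population_from_tables(dosages: np.ndarray, annot: pd.DataFrame, seed: int | None = None) -> GenomePopulation:
    """Rebuild a :class:`GenomePopulation` from the dosage + annotation tables."""
    return GenomePopulation(
        dosages=dosages.astype(np.int8),
        block_of_locus=annot["block"].to_numpy(),
        is_qtl=annot["is_qtl"].to_numpy().astype(bool),
        ld_class=annot["ld_class"].to_numpy(dtype=object),
        seed=seed,
    )


def write_vcf(pop: GenomePopulation, path: str | Path, chrom: str = "1") -> None:
    """Write dosages as an unphased VCF (heterozygotes coded 0/1, phase arbitrary)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind{i}" for i in range(pop.n_individuals))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(pop.n_loci):
            gts = "\t".join(gt_strings[int(d)] for d in pop.dosages[:, j])
            fh.write(f"{chrom}\t{j + 1}\tL{j}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_dosages(path: str | Path) -> np.ndarray:
    """Alternate-allele dosage matrix (individuals x loci) from VCF GT fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    cols = []
    for variant in vcf:
        gt = np.asarray(variant.gt_types, dtype=np.int8)  # 0/1/2, 3=missing
        if np.any(gt == 3):
            raise ValueError(f"missing genotypes at {variant.ID}")
        cols.append(gt)
    vcf.close()
    if not cols:
        raise ValueError("VCF contains no variants")
    return np.column_stack(cols)
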