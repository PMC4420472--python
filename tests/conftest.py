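import numpy as np
import pytest

from genoherit.synthetic_genomes import BlockSpec, GenomePopulation, assign_qtl, simulate_population
from genoherit.trait_sim import make_architecture, simulate_phenotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20150505)


@pytest.fixture(scope="session")
def small_pop():
    """A 60-block x 5-locus population of 800 individuals with 12 QTL."""
    spec = BlockSpec(n_blocks=60, loci_per_block=5, copy_prob=0.8)
    pop = simulate_population(spec, 800, 41)
    return assign_qtl(pop, 12, "block_random", np.random.default_rng(42))


@pytest.fixture(scope="session")
def small_trait(small_pop):
    arch = make_architecture(small_pop, target_h2=0.5, rng=np.random.default_rng(7))
    phen = simulate_phenotypes(small_pop, arch, np.random.default_rng(8))
    return arch, phen


def manual_population(dosages, block_of_locus=None, qtl=()):
    """Build a GenomePopulation directly from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_loci = dosages.shape[1]
    blocks = np.asarray(block_of_locus) if block_of_locus is not None else np.arange(n_loci)
    is_qtl = np.zeros(n_loci, dtype=bool)
    is_qtl[list(qtl)] = True
    cls = np.full(n_loci, "MRK.LE", dtype=object)
    qtl_blocks = np.unique(blocks[is_qtl]) if is_qtl.any() else np.array([])
    cls[np.isin(blocks, qtl_blocks)] = "MRK.LD"
    cls[is_qtl] = "QTL"
    return GenomePopulation(dosages=dosages, block_of_locus=blocks, is_qtl=is_qtl, ld_class=cls)
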