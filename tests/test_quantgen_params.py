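"""Population-parameter algebra: effects, variances, heritabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoherit.quantgen_params import (
    SingularCovarianceError,
    additive_effects,
    additive_variance,
    blocked_variance_decomposition,
    covariance_blocks,
    genomic_heritability,
    genomic_variance,
    independent_pairs_variance,
    marker_effects,
    naive_statistical_variance,
    population_params,
    sample_genomic_variance,
    variance_decomposition,
)
from genoherit.synthetic_genomes import BlockSpec, assign_qtl, simulate_population
from genoherit.trait_sim import TraitArchitecture, make_architecture
from conftest import manual_population


def random_system(rng, q=2, p=4, n=400):
    """A small full-rank population with q QTL among p+q loci."""
    dos = rng.integers(0, 3, size=(n, p + q)).astype(np.int8)
    pop = manual_population(dos, block_of_locus=np.zeros(p + q, int), qtl=tuple(range(q)))
    alpha = rng.standard_normal(q)
    return pop, alpha


class TestCovarianceBlocks:
    def test_constant_population_gives_zero_matrices(self):
        pop = manual_population(np.ones((6, 4), dtype=int), qtl=(0,))
        sz, sx, sxz = covariance_blocks(pop)
        assert not sz.any() and not sx.any() and not sxz.any()

    def test_single_locus_variance_matches_two_pass_formula(self, rng):
        dos = rng.integers(0, 3, size=(50, 2)).astype(np.int8)
        pop = manual_population(dos, qtl=(0,))
        sz, _, _ = covariance_blocks(pop)
        x = dos[:, 0].astype(float)
        expected = np.sum((x - x.mean()) ** 2) / x.size
        assert sz[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_hardy_weinberg_dosage_variance(self):
        # HW: Var(dosage) = 2 theta (1 - theta) = 0.42 at theta = 0.3
        rng = np.random.default_rng(12)
        dos = (rng.random((100_000, 2, 2)) < 0.3).sum(axis=2).astype(np.int8)
        pop = manual_population(dos, qtl=(0,))
        sz, sx, _ = covariance_blocks(pop)
        assert sz[0, 0] == pytest.approx(0.42, abs=0.01)
        assert sx[0, 0] == pytest.approx(0.42, abs=0.01)

    def test_empty_partition_rejected(self):
        pop = manual_population(np.eye(4, dtype=int), qtl=())
        with pytest.raises(ValueError, match="empty"):
            covariance_blocks(pop)


class TestAdditiveEffects:
    def test_recovers_generating_effects(self, rng):
        pop, alpha_true = random_system(rng, q=3, p=2)
        z = pop.dosages[:, :3].astype(float)
        z -= z.mean(axis=0)
        g = z @ alpha_true
        sigma_z = z.T @ z / z.shape[0]
        sigma_zg = z.T @ g / z.shape[0]
        np.testing.assert_allclose(additive_effects(sigma_z, sigma_zg), alpha_true, atol=1e-10)

    def test_scalar_case(self):
        assert additive_effects([[2.0]], [1.0]) == pytest.approx([0.5])

    def test_projection_residual_orthogonal_with_dominance(self, rng):
        # add a dominance term; alpha is then the best linear projection and
        # the residual has zero population covariance with every dosage
        pop, _ = random_system(rng, q=2, p=0, n=600)
        z = pop.dosages[:, :2].astype(float)
        zc = z - z.mean(axis=0)
        g = 1.5 * zc[:, 0] - 0.5 * zc[:, 1] + 2.0 * (z[:, 0] == 1)
        g -= g.mean()
        n = z.shape[0]
        alpha = additive_effects(zc.T @ zc / n, zc.T @ g / n)
        resid = g - zc @ alpha
        np.testing.assert_allclose(zc.T @ resid / n, 0.0, atol=1e-10)

    def test_singular_sigma_z_raises_with_loci(self):
        sigma = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SingularCovarianceError):
            additive_effects(sigma, [1.0, 1.0])


class TestVariances:
    def test_additive_variance_le_closed_form(self):
        # two QTL in LE at HW: sigma2_a = sum_j 2 theta_j (1-theta_j) alpha_j^2
        t1, t2, a1, a2 = 0.2, 0.4, 1.3, -0.7
        sigma_z = np.diag([2 * t1 * (1 - t1), 2 * t2 * (1 - t2)])
        expected = 2 * t1 * (1 - t1) * a1**2 + 2 * t2 * (1 - t2) * a2**2
        assert additive_variance([a1, a2], sigma_z) == pytest.approx(expected)

    def test_zero_effects_zero_variance(self):
        assert additive_variance([0.0, 0.0], np.eye(2)) == 0.0

    def test_quadratic_form_matches_enumeration(self, rng):
        pop, alpha = random_system(rng, q=5, p=1, n=300)
        z = pop.dosages[:, :5].astype(float)
        zc = z - z.mean(axis=0)
        sigma_z = zc.T @ zc / z.shape[0]
        brute = (zc @ alpha).var()
        assert additive_variance(alpha, sigma_z) == pytest.approx(brute, rel=1e-10)


class TestMarkerEffects:
    def test_worked_example_one_qtl_two_markers(self):
        sigma_x = [[1.0, 0.5], [0.5, 1.0]]
        sigma_xz = [[0.5], [0.5]]
        beta = marker_effects(sigma_x, sigma_xz, [1.0])
        np.testing.assert_allclose(beta, [1 / 3, 1 / 3], atol=1e-12)

    def test_markers_identical_to_qtl_recover_alpha(self, rng):
        pop, alpha = random_system(rng, q=2, p=3)
        sz, sx, sxz = covariance_blocks(pop, qtl_idx=[0, 1], marker_idx=[0, 1, 2, 3, 4])
        beta = marker_effects(sx, sxz, alpha)
        np.testing.assert_allclose(beta[:2], alpha, atol=1e-8)
        np.testing.assert_allclose(beta[2:], 0.0, atol=1e-8)

    def test_matches_ols_oracle(self, rng):
        # beta equals OLS of g on the marker dosages over the population
        pop, alpha = random_system(rng, q=2, p=4)
        z = pop.dosages[:, :2].astype(float)
        zc = z - z.mean(axis=0)
        g = zc @ alpha
        X = pop.dosages[:, 2:].astype(float)
        Xc = X - X.mean(axis=0)
        ols, *_ = np.linalg.lstsq(Xc, g, rcond=None)
        sz, sx, sxz = covariance_blocks(pop, qtl_idx=[0, 1], marker_idx=[2, 3, 4, 5])
        np.testing.assert_allclose(marker_effects(sx, sxz, alpha), ols, atol=1e-8)

    def test_duplicate_markers_fail_loudly(self, rng):
        dos = rng.integers(0, 3, size=(100, 3)).astype(np.int8)
        dos = np.column_stack([dos, dos[:, 2]])  # marker 3 duplicates marker 2
        pop = manual_population(dos, qtl=(0,))
        sz, sx, sxz = covariance_blocks(pop, qtl_idx=[0], marker_idx=[1, 2, 3])
        with pytest.raises(SingularCovarianceError) as err:
            marker_effects(sx, sxz, [1.0])
        assert err.value.offending  # names the collinear columns


class TestGenomicVariance:
    def test_worked_example_third_vs_two_ninths(self):
        sigma_x = np.array([[1.0, 0.5], [0.5, 1.0]])
        sigma_zx = np.array([[0.5, 0.5]])
        sg2 = genomic_variance([1.0], sigma_zx, sigma_x)
        assert sg2 == pytest.approx(1 / 3, abs=1e-12)
        beta = marker_effects(sigma_x, sigma_zx.T, [1.0])
        ld_ignoring = float(np.sum(np.diag(sigma_x) * beta**2))
        assert ld_ignoring == pytest.approx(2 / 9, abs=1e-12)
        assert beta @ sigma_x @ beta == pytest.approx(sg2, abs=1e-12)

    def test_markers_equal_qtl_no_missing_variance(self, rng):
        pop, alpha = random_system(rng, q=3, p=0)
        sz, sx, sxz = covariance_blocks(pop, qtl_idx=[0, 1, 2], marker_idx=[0, 1, 2])
        s2a, s2g, s2gbar = variance_decomposition(alpha, sz, sxz.T, sx)
        assert s2g == pytest.approx(s2a, rel=1e-10)
        assert s2gbar == pytest.approx(0.0, abs=1e-8)

    def test_beta_sigma_beta_matches_enumeration(self, rng):
        pop, alpha = random_system(rng, q=2, p=4)
        sz, sx, sxz = covariance_blocks(pop, qtl_idx=[0, 1], marker_idx=[2, 3, 4, 5])
        beta = marker_effects(sx, sxz, alpha)
        X = pop.dosages[:, 2:].astype(float)
        Xc = X - X.mean(axis=0)
        assert genomic_variance(alpha, sxz.T, sx) == pytest.approx((Xc @ beta).var(), rel=1e-10)

    def test_residual_orthogonal_to_markers(self, rng):
        pop, alpha = random_system(rng, q=2, p=4)
        sz, sx, sxz = covariance_blocks(pop, qtl_idx=[0, 1], marker_idx=[2, 3, 4, 5])
        beta = marker_effects(sx, sxz, alpha)
        z = pop.dosages[:, :2].astype(float)
        X = pop.dosages[:, 2:].astype(float)
        xi = (z - z.mean(0)) @ alpha - (X - X.mean(0)) @ beta
        cov = (X - X.mean(0)).T @ xi / X.shape[0]
        np.testing.assert_allclose(cov, 0.0, atol=1e-10)

    def test_monotone_in_marker_span(self, rng):
        # adding markers never decreases sigma2_g (larger projection span)
        pop, alpha = random_system(rng, q=2, p=6)
        prev = 0.0
        for p_used in (1, 2, 4, 6):
            idx = list(range(2, 2 + p_used))
            _, sx, sxz = covariance_blocks(pop, qtl_idx=[0, 1], marker_idx=idx)
            sg2 = genomic_variance(alpha, sxz.T, sx)
            assert sg2 >= prev - 1e-10
            prev = sg2


class TestRotationInvariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_marker_recoding(self, seed):
        rng = np.random.default_rng(seed)
        pop, alpha = random_system(rng, q=2, p=4)
        sz, sx, sxz = covariance_blocks(pop, qtl_idx=[0, 1], marker_idx=[2, 3, 4, 5])
        sg2 = genomic_variance(alpha, sxz.T, sx)
        A = rng.standard_normal((4, 4))
        while abs(np.linalg.det(A)) < 1e-3:
            A = rng.standard_normal((4, 4))
        sx_t = A @ sx @ A.T
        sxz_t = A @ sxz
        assert genomic_variance(alpha, sxz_t.T, sx_t) == pytest.approx(sg2, rel=1e-8)


class TestHeritabilities:
    def test_single_pair_law(self):
        # hg2 = r^2 h2 for one marker-QTL pair
        h2g, missing = genomic_heritability(sigma2_g=0.25 * 2.0, sigma2_a=2.0, h2=0.5)
        assert h2g == pytest.approx(0.25 * 0.5)
        assert missing == pytest.approx(0.75)

    def test_no_missing_when_variances_equal(self):
        h2g, missing = genomic_heritability(1.7, 1.7, 0.42)
        assert h2g == pytest.approx(0.42)
        assert missing == pytest.approx(0.0)

    def test_zero_r2_zero_heritability(self):
        h2g, missing = genomic_heritability(0.0, 1.0, 0.5)
        assert h2g == 0.0 and missing == 1.0

    def test_zero_additive_variance_rejected(self):
        with pytest.raises(ValueError, match="sigma2_a"):
            genomic_heritability(0.0, 0.0, 0.5)


class TestIndependentPairs:
    def test_perfect_ld_pair(self):
        assert independent_pairs_variance([(0.42, 1.0, 2.0)]) == pytest.approx(0.42 * 4.0)

    def test_zero_r2_pairs(self):
        assert independent_pairs_variance([(0.5, 0.0, 1.0)] * 3) == 0.0

    def test_equals_block_diagonal_genomic_variance(self, rng):
        # three pairs; the pairwise sums must equal the general formula on
        # the induced block-diagonal system
        pairs = []
        sx_blocks, sxz_rows, alphas = [], [], []
        for _ in range(3):
            vz = rng.uniform(0.2, 0.5)
            vx = rng.uniform(0.2, 0.5)
            r = rng.uniform(-0.9, 0.9)
            cov = r * np.sqrt(vz * vx)
            a = rng.standard_normal()
            pairs.append((vz, r * r, a))
            sx_blocks.append(vx)
            sxz_rows.append(cov)
            alphas.append(a)
        sx = np.diag(sx_blocks)
        sxz = np.diag(sxz_rows)  # pair j marker covaries only with pair j QTL
        expected = genomic_variance(alphas, sxz.T, sx)
        assert independent_pairs_variance(pairs) == pytest.approx(expected, abs=1e-10)


class TestSampleGenomicVariance:
    def test_definitional_agreement_on_full_population(self, rng):
        pop, alpha = random_system(rng, q=2, p=4)
        _, sx, sxz = covariance_blocks(pop, qtl_idx=[0, 1], marker_idx=[2, 3, 4, 5])
        beta = marker_effects(sx, sxz, alpha)
        X = pop.dosages[:, 2:].astype(float)
        Xc = X - X.mean(axis=0)
        assert sample_genomic_variance(Xc, beta) == pytest.approx(
            genomic_variance(alpha, sxz.T, sx), rel=1e-10
        )

    def test_zero_beta(self, rng):
        X = rng.standard_normal((10, 3))
        assert sample_genomic_variance(X - X.mean(0), np.zeros(3)) == 0.0

    def test_subsample_consistency(self):
        # plug-in value approaches the population parameter as n grows
        pop = simulate_population(BlockSpec(n_blocks=30, loci_per_block=5), 10_000, 77)
        pop = assign_qtl(pop, 6, "block_random", 5)
        arch = make_architecture(pop, 0.5, 6)
        mrk = np.flatnonzero(~pop.is_qtl)
        _, sx, sxz = covariance_blocks(pop, pop.qtl_indices, mrk)
        beta = marker_effects(sx, sxz, arch.alpha)
        sg2 = genomic_variance(arch.alpha, sxz.T, sx)
        sub = np.random.default_rng(9).choice(10_000, 10_000, replace=False)
        X = pop.dosages[np.sort(sub)][:, mrk].astype(float)
        Xc = X - X.mean(axis=0)
        assert sample_genomic_variance(Xc, beta) == pytest.approx(sg2, rel=0.02)


class TestNaiveStatisticalVariance:
    def test_standardized_is_p_sigma2b(self):
        assert naive_statistical_variance(None, 0.3, standardized=True, p=10) == pytest.approx(3.0)

    def test_hw_arithmetic(self):
        assert naive_statistical_variance([0.5] * 10, 1.0) == pytest.approx(5.0)

    def test_agrees_with_quadratic_form_when_sigma_x_diagonal(self):
        freqs = np.array([0.2, 0.35, 0.45])
        b0 = 0.8
        sx = np.diag(2 * freqs * (1 - freqs))
        beta = np.full(3, b0)
        assert naive_statistical_variance(freqs, b0**2) == pytest.approx(beta @ sx @ beta)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            naive_statistical_variance([0.0, 0.5], 1.0)


class TestWholePopulationDrivers:
    def test_dense_and_blocked_paths_agree(self):
        # the dense path sees the realized cross-block covariances (O(1/sqrt n))
        # that the blocked path treats as exactly zero, so the two converge
        # as the population grows
        pop = simulate_population(BlockSpec(n_blocks=40, loci_per_block=5), 8000, 19)
        pop = assign_qtl(pop, 8, "block_random", 20)
        arch = make_architecture(pop, 0.5, 3)
        mrk = np.flatnonzero(~pop.is_qtl)
        params = population_params(pop, arch)
        s2a_b, s2g_b, _ = blocked_variance_decomposition(pop, arch, mrk)
        assert s2a_b == pytest.approx(params.sigma2_a, rel=0.05)
        assert s2g_b == pytest.approx(params.sigma2_g, rel=0.15)
        assert params.sigma2_a == pytest.approx(params.sigma2_g + params.sigma2_gbar, rel=1e-10)
        assert 0.0 < params.h2_g <= params.h2 <= 1.0

    def test_locus_cap_enforced(self, small_pop):
        arch = make_architecture(small_pop, 0.5, 3)
        with pytest.raises(ValueError, match="capped"):
            population_params(small_pop, arch, locus_cap=10)
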