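import numpy as np
import pytest
from scipy.stats import spearmanr

from bioesn import (
    DegenerateInputError,
    ValidationError,
    generate_synthetic_connectome,
    make_bio_no_rank,
    make_bio_rank,
    make_random_density,
    make_random_full,
    make_random_k,
    sample_link_weights,
    scale_spectral_radius,
)
from bioesn.bio2art import upscale
from bioesn.surrogates import rank_assign


class TestSampleLinkWeights:
    def test_empty(self):
        assert sample_link_weights(0, 0).size == 0

    def test_mean_within_clt_bound(self):
        w = sample_link_weights(10**5, seed=1)
        # Uniform[-1,1]: sd = 2/sqrt(12); 3-sigma bound on the sample mean
        assert abs(w.mean()) < 3 * (2 / np.sqrt(12)) / np.sqrt(10**5)

    def test_bounds_and_no_zeros(self):
        w = sample_link_weights(10**4, seed=2)
        assert np.all(np.abs(w) <= 1) and np.all(w != 0)

    def test_determinism(self):
        np.testing.assert_array_equal(
            sample_link_weights(100, seed=3), sample_link_weights(100, seed=3)
        )


class TestRankAssign:
    def test_three_link_toy(self):
        # strengths 5, 1, 3 with sampled {-0.4, 0.2, 0.9}:
        # weakest link (1) -> -0.4, middle (3) -> 0.2, strongest (5) -> 0.9
        out = rank_assign([5.0, 1.0, 3.0], [-0.4, 0.2, 0.9])
        np.testing.assert_allclose(out, [0.9, -0.4, 0.2])

    def test_ties_broken_by_position(self):
        out = rank_assign([2.0, 2.0], [0.5, -0.5])
        np.testing.assert_allclose(out, [-0.5, 0.5])


class TestBioRank:
    def test_toy_assignment(self, toy_connectome):
        r = make_bio_rank(toy_connectome, seed=0)
        w = r.weights
        # a->b (5) strongest, c->a (3) middle, b->c (1) weakest
        assert w[0, 1] > w[2, 0] > w[1, 2]

    def test_mask_equals_empirical(self, modular_connectome):
        r = make_bio_rank(modular_connectome, seed=1)
        np.testing.assert_array_equal(r.mask, modular_connectome.mask)

    def test_perfect_spearman(self, modular_connectome):
        r = make_bio_rank(modular_connectome, seed=2)
        m = modular_connectome.mask
        rho, _ = spearmanr(modular_connectome.weights[m], r.weights[m])
        assert rho == pytest.approx(1.0)

    def test_single_link(self):
        w = np.zeros((2, 2))
        w[0, 1] = 7.0
        from bioesn import Connectome

        r = make_bio_rank(Connectome(w), seed=3)
        assert r.n_links == 1 and r.weights[0, 1] != 0

    def test_no_links_rejected(self):
        from bioesn import Connectome

        with pytest.raises(DegenerateInputError):
            make_bio_rank(Connectome(np.zeros((3, 3))), seed=0)

    def test_upscaled_interareal_links_keep_rank_but_intrinsic_do_not(self):
        c = generate_synthetic_connectome(6, 2, 0.5, seed=4)
        u = upscale(c, 3, "heterogeneous", seed=5)
        r = make_bio_rank(u, seed=6)
        aon = u.area_of_neuron
        links = np.argwhere(r.mask)
        inter = aon[links[:, 0]] != aon[links[:, 1]]
        iw = u.weights[links[inter, 0], links[inter, 1]]
        rw = r.weights[links[inter, 0], links[inter, 1]]
        rho, _ = spearmanr(iw, rw)
        assert rho == pytest.approx(1.0)


class TestBioNoRank:
    def test_mask_equals_empirical(self, modular_connectome):
        r = make_bio_no_rank(modular_connectome, seed=1)
        np.testing.assert_array_equal(r.mask, modular_connectome.mask)

    def test_rank_structure_destroyed_on_average(self):
        # ~10^4 links; null Spearman sd ~ 1/sqrt(n-1) ~ 0.01
        c = generate_synthetic_connectome(105, 1, 0.92, seed=9)
        m = c.mask
        rhos = [
            spearmanr(c.weights[m], make_bio_no_rank(c, seed=s).weights[m])[0]
            for s in range(100)
        ]
        assert abs(np.mean(rhos)) < 0.05


class TestRandomDensity:
    def test_link_count_conserved(self, modular_connectome):
        r = make_random_density(modular_connectome, seed=0)
        assert r.n_links == modular_connectome.n_links

    def test_full_stays_full(self):
        c = generate_synthetic_connectome(8, 1, 1.0, seed=1)
        assert make_random_density(c, seed=2).n_links == 56

    def test_uniform_pair_inclusion(self):
        c = generate_synthetic_connectome(20, 1, 0.3, seed=3)
        n = 20
        counts = np.zeros((n, n))
        n_seeds = 200
        for s in range(n_seeds):
            counts += make_random_density(c, seed=s).mask
        d = c.density
        off = ~np.eye(n, dtype=bool)
        freq = counts[off] / n_seeds
        sd = np.sqrt(d * (1 - d) / n_seeds)
        # binomial sampling check: nearly all pairs within 3 sd of the density
        assert np.mean(np.abs(freq - d) <= 3 * sd) > 0.97


class TestRandomK:
    def test_fixed_in_degree(self):
        r = make_random_k(50, 10, seed=0)
        in_deg = r.mask.sum(axis=0)
        assert np.all(in_deg == 10) and r.n_links == 500

    def test_fixed_out_degree_variant(self):
        r = make_random_k(20, 4, seed=1, degree="out")
        assert np.all(r.mask.sum(axis=1) == 4)

    def test_k_equals_n_minus_1_is_full(self):
        r = make_random_k(5, 4, seed=2)
        assert r.n_links == 20

    def test_k_too_large_rejected(self):
        with pytest.raises(DegenerateInputError):
            make_random_k(5, 5, seed=0)


class TestRandomFull:
    def test_complete_graph(self):
        r = make_random_full(10, seed=0)
        assert r.n_links == 90
        assert not np.any(np.diag(r.mask))

    def test_same_mask_different_weights_across_seeds(self):
        a, b = make_random_full(6, seed=1), make_random_full(6, seed=2)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert np.any(a.weights != b.weights)

    def test_too_small_rejected(self):
        with pytest.raises(DegenerateInputError):
            make_random_full(1, seed=0)


class TestSpectralScaling:
    def test_two_cycle_exact(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])  # eigenvalues +/-1
        scaled = scale_spectral_radius(w, 0.99)
        np.testing.assert_allclose(scaled, [[0.0, 0.99], [0.99, 0.0]])

    def test_resulting_radius_matches_target(self, modular_connectome):
        r = make_bio_no_rank(modular_connectome, seed=4)
        scaled = scale_spectral_radius(r, 0.99)
        assert scaled.spectral_radius == pytest.approx(0.99, rel=1e-8)

    def test_mask_unchanged(self, modular_connectome):
        r = make_bio_rank(modular_connectome, seed=5)
        np.testing.assert_array_equal(scale_spectral_radius(r, 0.5).mask, r.mask)

    def test_nilpotent_rejected(self):
        w = np.triu(np.ones((4, 4)), 1)
        with pytest.raises(DegenerateInputError):
            scale_spectral_radius(w, 0.99)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValidationError):
            scale_spectral_radius(np.eye(2), -1.0)


@pytest.mark.parametrize("build", [
    lambda c, s: make_bio_rank(c, s),
    lambda c, s: make_bio_no_rank(c, s),
    lambda c, s: make_random_density(c, s),
    lambda c, s: make_random_k(c.n_areas, 3, s),
    lambda c, s: make_random_full(c.n_areas, s),
], ids=["bio_rank", "bio_no_rank", "random_density", "random_k", "random_full"])
def test_condition_invariants(build, small_connectome):
    """Zero diagonal, weights in [-1, 1] pre-scaling, seed determinism."""
    r1 = build(small_connectome, 7)
    r2 = build(small_connectome, 7)
    assert np.all(np.diag(r1.weights) == 0)
    assert np.all(np.abs(r1.weights) <= 1)
    np.testing.assert_array_equal(r1.weights, r2.weights)
    # mask/weights equivalence
    np.testing.assert_array_equal(r1.weights != 0, r1.mask)
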