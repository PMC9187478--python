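"""Random-walker core: weights, Laplacian/incidence, harmonic solve, argmax."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rwct import (
    GridImage,
    SeedMap,
    build_incidence,
    build_laplacian,
    compute_edge_weights,
    lattice_edges,
    rw_segment,
    solve_dirichlet,
)
from rwct.rw_core import DisconnectedSeedError


def dense_dirichlet_oracle(lap_dense, seed_idx, seed_labels):
    """Dense direct solve of the seeded Laplace system, one label at a time."""
    n = lap_dense.shape[0]
    labels = np.unique(seed_labels)
    unseeded = np.setdiff1d(np.arange(n), seed_idx)
    probs = np.zeros((n, len(labels)))
    for k, lab in enumerate(labels):
        b = (seed_labels == lab).astype(float)
        probs[seed_idx, k] = b
        if len(unseeded):
            a = lap_dense[np.ix_(unseeded, unseeded)]
            rhs = -lap_dense[np.ix_(unseeded, seed_idx)] @ b
            probs[unseeded, k] = np.linalg.solve(a, rhs)
    return probs, labels


class TestEdgeWeights:
    def test_constant_image_gives_unit_weights(self):
        g = compute_edge_weights(GridImage(np.full((4, 5), 3.7)), beta=50.0)
        assert np.allclose(g.weights, 1.0)

    def test_beta_zero_gives_unit_weights(self):
        rng = np.random.default_rng(0)
        g = compute_edge_weights(GridImage(rng.random((4, 4))), beta=0.0)
        assert np.allclose(g.weights, 1.0)

    def test_unit_contrast_closed_form(self):
        # adjacent normalized intensities 0 and 1 with beta=1 -> e^-1
        img = GridImage(np.array([[0.0, 1.0]]))
        g = compute_edge_weights(img, beta=1.0)
        assert g.weights[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    @pytest.mark.parametrize("connectivity,expected", [(4, 2 * 3 * 4 - 3 - 4), (8, 17 + 2 * 2 * 3)])
    def test_edge_count_matches_lattice(self, connectivity, expected):
        # 3x4 lattice: 4-conn has h(w-1)+w(h-1)=9+8=17 edges; 8-conn adds 2(h-1)(w-1)=12
        edges = lattice_edges((3, 4), connectivity)
        assert len(edges) == expected

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            compute_edge_weights(GridImage(np.zeros((2, 2))), beta=-1.0)

    def test_non_finite_intensity_rejected(self):
        with pytest.raises(ValueError):
            GridImage(np.array([[0.0, np.nan]]))


class TestMatrices:
    def test_two_node_laplacian(self):
        img = GridImage(np.array([[0.0, 0.5]]))
        g = compute_edge_weights(img, beta=2.0)
        v = g.weights[0]
        lap = build_laplacian(g).toarray()
        assert np.allclose(lap, [[v, -v], [-v, v]])

    def test_incidence_path_graph(self):
        g = compute_edge_weights(GridImage(np.zeros((1, 3))))
        b = build_incidence(g).toarray()
        assert np.array_equal(b, [[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])

    def test_incidence_factorization_and_row_sums(self):
        """B^T diag(v) B must reproduce the Laplacian on a random-weight lattice."""
        rng = np.random.default_rng(42)
        img = GridImage(rng.random((3, 3)))
        g = compute_edge_weights(img, beta=30.0, connectivity=8)
        lap = build_laplacian(g).toarray()
        b = build_incidence(g).toarray()
        assert np.allclose(b.T @ np.diag(g.weights) @ b, lap, atol=1e-12)
        assert np.allclose(lap.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(lap, lap.T)
        eigs = np.linalg.eigvalsh(lap)
        assert eigs.min() >= -1e-10  # positive semidefinite


class TestDirichletSolve:
    def test_chain_midpoint_symmetry(self):
        img = GridImage(np.zeros((1, 3)))
        g = compute_edge_weights(img)
        prob = solve_dirichlet(build_laplacian(g), SeedMap.from_points(
            [(0, 0, 1), (0, 2, 2)]), img.shape)
        assert prob.probabilities[1] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_chain_of_four_hand_solved(self):
        # uniform 1x4 chain, seeds at the ends: interior left-label potentials 2/3, 1/3
        img = GridImage(np.zeros((1, 4)))
        g = compute_edge_weights(img)
        prob = solve_dirichlet(build_laplacian(g), SeedMap.from_points(
            [(0, 0, 1), (0, 3, 2)]), img.shape)
        left = prob.image(1).ravel()
        assert left == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0], abs=1e-10)

    def test_seeds_are_one_hot(self):
        rng = np.random.default_rng(1)
        img = GridImage(rng.random((5, 5)))
        g = compute_edge_weights(img, beta=40.0)
        seeds = SeedMap.from_points([(0, 0, 1), (4, 4, 2), (2, 2, 3)])
        prob = solve_dirichlet(build_laplacian(g), seeds, img.shape)
        assert np.array_equal(prob.probabilities[0], [1.0, 0.0, 0.0])
        assert np.array_equal(prob.probabilities[24], [0.0, 1.0, 0.0])
        assert np.array_equal(prob.probabilities[12], [0.0, 0.0, 1.0])

    def test_single_label_rejected(self):
        img = GridImage(np.zeros((2, 2)))
        g = compute_edge_weights(img)
        with pytest.raises(ValueError, match="two labels"):
            solve_dirichlet(build_laplacian(g), SeedMap.from_points([(0, 0, 1)]), img.shape)

    def test_disconnected_pixel_diagnostic(self):
        """An isolated unseeded node must be reported, not silently solved."""
        import scipy.sparse as sp

        lap = sp.block_diag([
            np.array([[1.0, -1.0], [-1.0, 1.0]]),
            np.array([[0.0]]),  # isolated node, index 2
        ]).tocsr()
        seeds = SeedMap.from_points([(0, 0, 1), (0, 1, 2)])
        with pytest.raises(DisconnectedSeedError, match="2"):
            solve_dirichlet(lap, seeds, (1, 3))

    @pytest.mark.parametrize("shape,n_labels", [((7, 9), 2), ((10, 10), 3), ((3, 10), 4)])
    def test_sparse_matches_dense_oracle(self, shape, n_labels):
        """Sparse/iterative solution equals an independent dense direct solve."""
        rng = np.random.default_rng(shape[0] * 100 + n_labels)
        img = GridImage(rng.random(shape))
        # moderate beta keeps all edge weights well above the floor, so the
        # systems stay well-conditioned and two direct methods can agree to 1e-8
        g = compute_edge_weights(img, beta=10.0)
        lap = build_laplacian(g)
        pts = []
        flat_choices = rng.choice(shape[0] * shape[1], size=2 * n_labels, replace=False)
        for k, fi in enumerate(flat_choices):
            pts.append((fi // shape[1], fi % shape[1], k % n_labels + 1))
        seeds = SeedMap.from_points(pts)
        prob = solve_dirichlet(lap, seeds, shape)
        seed_idx, seed_labels = seeds.flat_indices(shape)
        oracle, labels = dense_dirichlet_oracle(lap.toarray(), seed_idx, seed_labels)
        assert np.array_equal(labels, prob.labels)
        assert np.max(np.abs(prob.probabilities - oracle)) <= 1e-8

    def test_probabilities_normalized_and_bounded(self, noisy_phantom):
        sample, seeds = noisy_phantom
        _, prob = rw_segment(sample.grid_image(), seeds)
        sums = prob.probabilities.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) <= 1e-6
        assert prob.probabilities.min() >= 0.0
        assert prob.probabilities.max() <= 1.0

    def test_maximum_principle(self):
        """Unseeded potentials stay within the range of their neighbours'."""
        rng = np.random.default_rng(3)
        img = GridImage(rng.random((8, 8)))
        g = compute_edge_weights(img, beta=50.0)
        seeds = SeedMap.from_points([(0, 0, 1), (7, 7, 2)])
        prob = solve_dirichlet(build_laplacian(g), seeds, img.shape)
        p = prob.image(1)
        seeded = seeds.to_raster(img.shape) > 0
        for r in range(8):
            for c in range(8):
                if seeded[r, c]:
                    continue
                nb = [p[r2, c2] for r2, c2 in ((r-1, c), (r+1, c), (r, c-1), (r, c+1))
                      if 0 <= r2 < 8 and 0 <= c2 < 8]
                assert min(nb) - 1e-8 <= p[r, c] <= max(nb) + 1e-8


class TestSegment:
    def test_step_image_exact_split(self, step_image, step_seeds):
        mask, _ = rw_segment(step_image, step_seeds, beta=90.0)
        expected = np.where(np.arange(6)[None, :] < 3, 1, 2) * np.ones((6, 1), dtype=int)
        assert np.array_equal(mask, expected)

    def test_uniform_image_boundary_equidistant(self):
        img = GridImage(np.zeros((5, 9)))
        seeds = SeedMap.from_points([(2, 0, 1), (2, 8, 2)])
        mask, prob = rw_segment(img, seeds)
        # columns strictly nearer a seed take its label; the centre column ties
        assert (mask[:, :4] == 1).all()
        assert (mask[:, 5:] == 2).all()
        assert np.allclose(prob.image(1)[:, 4], 0.5, atol=1e-10)

    def test_argmax_tie_breaks_to_smallest_label(self):
        img = GridImage(np.zeros((1, 3)))
        seeds = SeedMap.from_points([(0, 0, 1), (0, 2, 2)])
        mask, _ = rw_segment(img, seeds)
        assert mask[0, 1] == 1  # exact 0.5/0.5 tie

    def test_deterministic_repeat(self, noisy_phantom):
        sample, seeds = noisy_phantom
        m1, _ = rw_segment(sample.grid_image(), seeds)
        m2, _ = rw_segment(sample.grid_image(), seeds)
        assert np.array_equal(m1, m2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 100.0), offset=st.floats(-50.0, 50.0))
    def test_affine_intensity_invariance(self, scale, offset):
        """With rescaling on, a*I + b leaves the segmentation unchanged."""
        rng = np.random.default_rng(7)
        base = rng.random((6, 6))
        seeds = SeedMap.from_points([(0, 0, 1), (5, 5, 2)])
        m1, _ = rw_segment(GridImage(base), seeds, beta=40.0)
        m2, _ = rw_segment(GridImage(base * scale + offset), seeds, beta=40.0)
        assert np.array_equal(m1, m2)

    def test_matches_skimage_random_walker_on_step(self, step_image, step_seeds):
        """Independent implementation cross-check on a crisp two-region image."""
        skimage_seg = pytest.importorskip("skimage.segmentation")
        labels = step_seeds.to_raster(step_image.shape)
        ref = skimage_seg.random_walker(step_image.pixels, labels, beta=90.0, mode="bf")
        mask, _ = rw_segment(step_image, step_seeds, beta=90.0)
        assert np.array_equal(mask, ref)


class TestSeedMap:
    def test_conflicting_labels_rejected(self):
        with pytest.raises(ValueError, match="two different labels"):
            SeedMap.from_points([(0, 0, 1), (0, 0, 2)])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SeedMap.from_points([(5, 0, 1)]).validate_shape((3, 3))

    def test_raster_round_trip(self):
        raster = np.array([[0, 1], [2, 0]])
        seeds = SeedMap.from_raster(raster)
        assert np.array_equal(seeds.to_raster((2, 2)), raster)
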