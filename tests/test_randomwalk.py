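import numpy as np
import pytest
from scipy import ndimage

from noduleseg import metrics, phantom, randomwalk, seeding
from noduleseg.errors import DegenerateInputError, NumericalError, SeedingError
from oracles import dense_dirichlet


def seed_set(fg, bg):
    return seeding.SeedSet(foreground=frozenset(fg), background=frozenset(bg))


class TestDistanceFields:
    def test_distance_zero_on_own_seed_set(self):
        seeds = seed_set({(0, 0), (2, 3)}, {(4, 4)})
        df = randomwalk.distance_fields((5, 5), seeds)
        assert df.d_to_F[0, 0] == 0.0
        assert df.d_to_F[2, 3] == 0.0
        assert df.d_to_B[4, 4] == 0.0

    def test_line_distances_and_hausdorff(self):
        seeds = seed_set({(0, 0)}, {(0, 4)})
        df = randomwalk.distance_fields((1, 5), seeds)
        assert df.d_to_F[0, 3] == 3.0
        assert df.hausdorff_FB == 4.0

    def test_hausdorff_is_euclidean(self):
        seeds = seed_set({(0, 0)}, {(3, 4)})
        df = randomwalk.distance_fields((6, 6), seeds)
        assert df.hausdorff_FB == 5.0  # 3-4-5 triangle

    def test_empty_seed_set_rejected(self):
        with pytest.raises(SeedingError):
            randomwalk.distance_fields((4, 4), seed_set(set(), {(0, 0)}))


class TestSimilarityField:
    def test_partial_zero_gives_unit_similarity(self):
        seeds = seed_set({(0, 0)}, {(0, 4)})
        df = randomwalk.distance_fields((1, 5), seeds)
        G = randomwalk.similarity_field(df, partial=0.0)
        np.testing.assert_array_equal(G.G, 1.0)

    def test_direct_evaluation_of_similarity(self):
        df = randomwalk.DistanceFields(
            d_to_F=np.array([[2.0]]), d_to_B=np.array([[2.0]]), hausdorff_FB=4.0)
        G = randomwalk.similarity_field(df, partial=0.048)
        assert G.G[0, 0] == pytest.approx(np.exp(-0.048))

    def test_similarity_maximal_on_shortest_corridor(self):
        seeds = seed_set({(2, 0)}, {(2, 6)})
        df = randomwalk.distance_fields((5, 7), seeds)
        G = randomwalk.similarity_field(df, partial=0.048)
        # d_F + d_B is minimized on the straight line between the seeds
        assert G.G[2].min() >= G.G[0].max()

    def test_zero_hausdorff_rejected(self):
        df = randomwalk.DistanceFields(
            d_to_F=np.zeros((2, 2)), d_to_B=np.zeros((2, 2)), hausdorff_FB=0.0)
        with pytest.raises(DegenerateInputError):
            randomwalk.similarity_field(df)


class TestEdgeWeights:
    def test_equal_intensities_give_unit_weight(self):
        img = np.full((2, 2), 0.3)
        graph = randomwalk.edge_weights(img, None,
                                        randomwalk.WeightParams(beta2=0.0))
        np.testing.assert_allclose(graph.weights, 1.0)

    def test_gray_difference_weight_value(self):
        img = np.array([[0.0, 0.1]])
        graph = randomwalk.edge_weights(img, None,
                                        randomwalk.WeightParams(beta1=90.0, beta2=0.0))
        # max weight is rescaled to 1, and the only edge is the max itself;
        # check the relative weight against a two-value image instead
        img2 = np.array([[0.0, 0.0, 0.1]])
        graph2 = randomwalk.edge_weights(img2, None,
                                         randomwalk.WeightParams(beta1=90.0, beta2=0.0))
        np.testing.assert_allclose(sorted(graph2.weights),
                                   [np.exp(-0.9), 1.0])
        assert graph.weights[0] == 1.0

    def test_large_negative_beta2_does_not_overflow(self):
        img = np.full((3, 3), 0.5)
        G = randomwalk.SimilarityField(G=np.ones((3, 3)))
        graph = randomwalk.edge_weights(
            img, G, randomwalk.WeightParams(beta1=90.0, beta2=-51.5))
        assert np.all(np.isfinite(graph.weights))
        # exp(51.5) would overflow the edge scale; rescaling pins the max at 1
        assert graph.weights.max() == 1.0

    def test_weights_symmetric_under_image_flip(self, rng):
        img = rng.random((4, 4))
        params = randomwalk.WeightParams(beta2=0.0)
        g1 = randomwalk.edge_weights(img, None, params)
        g2 = randomwalk.edge_weights(img[::-1, ::-1].copy(), None, params)
        np.testing.assert_allclose(np.sort(g1.weights), np.sort(g2.weights))


class TestBuildLaplacian:
    def test_two_node_chain(self):
        graph = randomwalk.LatticeGraph(
            shape=(1, 2), edges=np.array([[0, 1]]), weights=np.array([1.0]))
        L = randomwalk.build_laplacian(graph).toarray()
        np.testing.assert_allclose(L, [[1, -1], [-1, 1]])

    def test_row_sums_zero(self, rng):
        img = rng.random((5, 4))
        graph = randomwalk.edge_weights(img, None, randomwalk.WeightParams(beta2=0.0))
        L = randomwalk.build_laplacian(graph)
        np.testing.assert_allclose(np.asarray(L.sum(axis=1)).ravel(), 0.0,
                                   atol=1e-12)

    def test_matches_incidence_form(self, rng):
        # L must equal A^T C A built from the edge-vertex incidence matrix
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [0, 4]])
        weights = rng.random(5) + 0.1
        graph = randomwalk.LatticeGraph(shape=(1, 5), edges=edges, weights=weights)
        L = randomwalk.build_laplacian(graph).toarray()
        A = np.zeros((5, 5))
        for e, (i, j) in enumerate(edges):
            A[e, i], A[e, j] = 1.0, -1.0
        np.testing.assert_allclose(L, A.T @ np.diag(weights) @ A)


class TestSolveDirichlet:
    def test_three_chain_symmetry(self):
        graph = randomwalk.LatticeGraph(
            shape=(1, 3), edges=np.array([[0, 1], [1, 2]]),
            weights=np.array([1.0, 1.0]))
        L = randomwalk.build_laplacian(graph)
        prob = randomwalk.solve_dirichlet(L, seed_set({(0, 0)}, {(0, 2)}), (1, 3))
        assert prob.p_fg[0, 1] == pytest.approx(0.5)

    def test_four_chain_interior_probabilities(self):
        graph = randomwalk.LatticeGraph(
            shape=(1, 4), edges=np.array([[0, 1], [1, 2], [2, 3]]),
            weights=np.ones(3))
        L = randomwalk.build_laplacian(graph)
        prob = randomwalk.solve_dirichlet(L, seed_set({(0, 0)}, {(0, 3)}), (1, 4))
        np.testing.assert_allclose(prob.p_fg[0], [1.0, 2 / 3, 1 / 3, 0.0])

    def test_seed_fidelity(self, rng):
        img = rng.random((4, 5))
        seeds = seed_set({(0, 0), (1, 1)}, {(3, 4), (2, 2)})
        graph = randomwalk.edge_weights(img, None, randomwalk.WeightParams(beta2=0.0))
        prob = randomwalk.solve_dirichlet(
            randomwalk.build_laplacian(graph), seeds, (4, 5))
        assert prob.p_fg[0, 0] == 1.0 and prob.p_fg[1, 1] == 1.0
        assert prob.p_fg[3, 4] == 0.0 and prob.p_fg[2, 2] == 0.0

    def test_matches_dense_oracle_on_small_lattices(self, rng):
        for trial in range(10):
            h, w = rng.integers(2, 5), rng.integers(2, 5)
            img = rng.random((h, w))
            flat = rng.permutation(h * w)
            fg = {(int(i // w), int(i % w)) for i in flat[:2]}
            bg = {(int(i // w), int(i % w)) for i in flat[2:4]}
            seeds = seed_set(fg, bg)
            graph = randomwalk.edge_weights(img, None,
                                            randomwalk.WeightParams(beta2=0.0))
            L = randomwalk.build_laplacian(graph)
            prob = randomwalk.solve_dirichlet(L, seeds, (h, w))
            fg_idx = np.array([r * w + c for r, c in sorted(fg)])
            bg_idx = np.array([r * w + c for r, c in sorted(bg)])
            expected = dense_dirichlet(h * w, graph.edges, graph.weights,
                                       fg_idx, bg_idx)
            np.testing.assert_allclose(prob.p_fg.ravel(), expected, atol=1e-8)

    def test_orphan_component_labelled_by_nearest_seed(self):
        # two disconnected 2-node chains; only the first carries seeds
        edges = np.array([[0, 1], [2, 3]])
        graph = randomwalk.LatticeGraph(shape=(1, 4), edges=edges,
                                        weights=np.ones(2))
        L = randomwalk.build_laplacian(graph)
        with pytest.warns(UserWarning, match="no seed"):
            prob = randomwalk.solve_dirichlet(
                L, seed_set({(0, 0)}, {(0, 1)}), (1, 4))
        # both orphans are nearer the background seed (column 1) than the
        # foreground seed (column 0), so the fallback labels them background
        assert prob.p_fg[0, 2] == 0.0
        assert prob.p_fg[0, 3] == 0.0


class TestLabelFromProbability:
    def test_certain_foreground(self):
        p = randomwalk.ProbabilityField(p_fg=np.array([[1.0, 0.0]]))
        np.testing.assert_array_equal(
            randomwalk.label_from_probability(p), [[True, False]])

    def test_tie_breaks_to_foreground(self):
        p = randomwalk.ProbabilityField(p_fg=np.array([[0.5]]))
        assert randomwalk.label_from_probability(p)[0, 0]


class TestSegmentLung:
    def test_noiseless_phantom_segmented_perfectly(self, noiseless_sample):
        mask, prob, seeds = randomwalk.segment_lung(noiseless_sample.image)
        c = metrics.confusion(mask, noiseless_sample.lung_mask)
        assert metrics.iou(c) == 1.0

    def test_noisy_phantom_high_iou(self, noisy_sample):
        mask, _, _ = randomwalk.segment_lung(noisy_sample.image)
        c = metrics.confusion(mask, noisy_sample.lung_mask)
        assert metrics.iou(c) >= 0.95

    def test_probabilities_respect_maximum_principle(self, noisy_sample):
        _, prob, seeds = randomwalk.segment_lung(noisy_sample.image)
        p = prob.p_fg
        fg, bg = seeds.indicator(p.shape)
        labeled = fg | bg
        # interior unlabeled pixels lie within the range of their neighbours
        neigh_max = ndimage.maximum_filter(p, footprint=np.array(
            [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool))
        neigh_min = ndimage.minimum_filter(p, footprint=np.array(
            [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool))
        interior = ~labeled
        assert np.all(p[interior] <= neigh_max[interior] + 1e-6)
        assert np.all(p[interior] >= neigh_min[interior] - 1e-6)

    def test_stage_error_carries_stage_name(self):
        img = np.full((32, 32), 0.5)  # constant: seeding must fail
        with pytest.raises(Exception) as excinfo:
            randomwalk.segment_lung(img)
        assert any("initial_lung_mask" in note
                   for note in getattr(excinfo.value, "__notes__", []))

    def test_deterministic(self, noisy_sample):
        m1, p1, _ = randomwalk.segment_lung(noisy_sample.image)
        m2, p2, _ = randomwalk.segment_lung(noisy_sample.image)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(p1.p_fg, p2.p_fg)
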