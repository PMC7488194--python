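"""Neuron placement, axon tracing, reflections and connection detection."""

import numpy as np
import pytest

from neuroculture.growth import (
    GrowthConfig,
    _min_dist_to_polyline,
    _trace,
    connection_geometry,
    detect_connections,
    grow_axon,
    grow_network,
    neuron_count,
    place_neurons,
)
from neuroculture.substrate import ObstacleSpec, SubstratePattern, build_pattern


class TestPlacement:
    def test_default_density_reproduces_published_counts(self, empty_pattern):
        assert neuron_count(empty_pattern, GrowthConfig().density) == 625
        assert neuron_count(build_pattern("empty", 4), GrowthConfig().density) == 2500
        assert neuron_count(build_pattern("empty", 2, 6), GrowthConfig().density) == 22500

    def test_positions_allowed_and_separated(self, crosses_pattern):
        cfg = GrowthConfig(density=120.0, seed=2)
        pts = place_neurons(crosses_pattern, cfg)
        assert len(pts) == neuron_count(crosses_pattern, 120.0)
        assert crosses_pattern.in_allowed_region(pts).all()
        from scipy.spatial.distance import pdist
        assert pdist(pts).min() >= cfg.soma_exclusion_radius

    def test_zero_density_gives_empty_network(self, empty_pattern):
        cfg = GrowthConfig(density=0.0)
        net = grow_network(empty_pattern, cfg, seed=0)
        assert net.n_neurons == 0 and net.n_edges == 0


class TestAxonTracing:
    def test_zero_jitter_no_obstacles_is_straight_with_drawn_length(self, empty_pattern):
        cfg = GrowthConfig(angular_jitter_sd=0.0)
        theta, length = 0.7, 0.35
        jitters = np.zeros(int(np.ceil(length / cfg.segment_length)))
        poly = _trace((0.0, 0.0), theta, length, jitters, empty_pattern, cfg)
        arc = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
        assert arc == pytest.approx(length, abs=1e-9)
        end = poly[-1]
        assert end == pytest.approx([length * np.cos(theta), length * np.sin(theta)], abs=1e-9)

    def test_rayleigh_mean_length(self, empty_pattern):
        cfg = GrowthConfig()
        rng = np.random.default_rng(0)
        lengths = [np.linalg.norm(np.diff(grow_axon((0.0, 0.0), empty_pattern, cfg, rng),
                                          axis=0), axis=1).sum()
                   for _ in range(300)]
        # axon length is conserved through rim reflections, so the sample mean
        # approaches the Rayleigh mean sigma * sqrt(pi / 2) ~ 1.128 mm
        assert np.mean(lengths) == pytest.approx(0.9 * np.sqrt(np.pi / 2), rel=0.05)

    def test_specular_reflection_matches_closed_form(self):
        # wall = left edge of a big square obstacle; incoming at 30 deg from
        # the wall normal; oracle: v' = v - 2 (v . n) n
        wall = SubstratePattern(diameter=4.0, obstacles=(
            ObstacleSpec("cross", (1.0, 0.0), (1.4, 1.4)),))  # square block at x >= 0.3
        cfg = GrowthConfig(angular_jitter_sd=0.0, segment_length=1.0)
        theta = np.deg2rad(-30.0)  # toward +x, 30 deg below horizontal
        start = np.array([0.3 - 0.2 * np.cos(np.deg2rad(30.0)), 0.2 * np.sin(np.deg2rad(30.0))])
        poly = _trace(start, theta, 0.4, np.zeros(1), wall, cfg)
        assert len(poly) == 3  # start, hit, end
        v_in = poly[1] - poly[0]
        v_out = poly[2] - poly[1]
        n = np.array([-1.0, 0.0])  # outward normal of the wall
        v_ref = v_in - 2 * (v_in @ n) * n
        assert v_out / np.linalg.norm(v_out) == pytest.approx(
            v_ref / np.linalg.norm(v_ref), abs=1e-6)

    def test_arc_length_conserved_through_reflections(self, small_crosses_net):
        for i in range(0, small_crosses_net.n_neurons, 7):
            poly = small_crosses_net.axons[i]
            arc = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
            assert arc == pytest.approx(small_crosses_net.axon_lengths[i], abs=1e-9)
            # no segment exceeds the configured step
            steps = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            assert steps.max() <= small_crosses_net.config.segment_length + 1e-12

    def test_confinement(self, small_crosses_net, crosses_pattern):
        verts = np.vstack(small_crosses_net.axons)
        assert crosses_pattern.in_allowed_region(verts).all()
        assert crosses_pattern.in_allowed_region(small_crosses_net.positions).all()


class TestConnections:
    def test_chain_connectivity(self):
        # axon of 1 crosses dendrite of 2, axon of 2 crosses dendrite of 3
        positions = np.array([[0.0, 0.0], [0.5, 0.0], [1.0, 0.0]])
        radii = np.array([0.05, 0.05, 0.05])
        axons = [np.array([[0.0, 0.0], [0.52, 0.0]]),
                 np.array([[0.5, 0.0], [0.5, 0.3], [1.0, 0.3], [1.0, 0.04]]),
                 np.array([[1.0, 0.0], [1.0, -0.4]])]
        adj = detect_connections(positions, radii, axons).toarray()
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 2] = 1
        assert np.array_equal(adj, expected)

    def test_isolated_axon(self):
        positions = np.array([[0.0, 0.0], [2.0, 2.0]])
        radii = np.array([0.05, 0.05])
        axons = [np.array([[0.0, 0.0], [0.3, 0.0]]), np.array([[2.0, 2.0], [2.3, 2.0]])]
        adj = detect_connections(positions, radii, axons)
        assert adj.nnz == 0

    def test_matches_brute_force_segment_disc_oracle(self):
        rng = np.random.default_rng(8)
        n = 20
        positions = rng.uniform(-1, 1, (n, 2))
        radii = rng.uniform(0.05, 0.2, n)
        axons = []
        for i in range(n):
            steps = rng.normal(0, 0.08, (12, 2))
            axons.append(positions[i] + np.vstack([[0, 0], np.cumsum(steps, axis=0)]))
        adj = detect_connections(positions, radii, axons).toarray()
        # oracle: exhaustive exact point-segment distance over all pairs
        expected = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = _min_dist_to_polyline(positions[j][None], axons[i])[0]
                expected[i, j] = 1 if d <= radii[j] else 0
        assert np.array_equal(adj, expected)

    def test_degree_sums_equal_edge_count(self, small_empty_net):
        assert small_empty_net.k_in.sum() == small_empty_net.n_edges
        assert small_empty_net.k_out.sum() == small_empty_net.n_edges

    def test_multiple_crossings_collapse_to_one_edge(self):
        positions = np.array([[0.0, 0.0], [0.5, 0.0]])
        radii = np.array([0.05, 0.05])
        wiggly = np.array([[0.0, 0.0], [0.5, 0.0], [0.5, 0.2], [0.45, 0.0], [0.5, -0.2]])
        adj = detect_connections(positions, radii, [wiggly, np.array([[0.5, 0.0], [0.5, 0.01]])])
        assert adj[0, 1] == 1 and adj.nnz == 1


class TestGeometryOfConnections:
    def test_cardinal_angles(self):
        from scipy import sparse

        from neuroculture.growth import StructuralNetwork
        positions = np.array([[0.0, 0.0], [0.0, -0.5], [0.3, 0.0]])
        adj = sparse.csr_matrix(np.array([[0, 1, 1], [0, 0, 0], [0, 0, 0]], dtype=np.int8))
        net = StructuralNetwork(positions=positions, dendrite_radii=np.full(3, 0.1),
                                axons=[np.empty((0, 2))] * 3, axon_lengths=np.zeros(3),
                                adjacency=adj, config=GrowthConfig(),
                                pattern_kind="custom", diameter=2.0)
        geo = connection_geometry(net)
        assert geo.distances == pytest.approx([0.5, 0.3])
        assert geo.angles == pytest.approx([180.0, 90.0])

    def test_empty_edges_warns(self, empty_pattern):
        net = grow_network(empty_pattern, GrowthConfig(density=0.0), seed=0)
        with pytest.warns(UserWarning):
            geo = connection_geometry(net)
        assert len(geo.distances) == 0


def test_mean_in_degree_decreases_with_cross_coverage():
    """Obstacle coverage monotonically suppresses connectivity."""
    k = []
    for kind in ("empty", "crosses_1array", "crosses_2arrays", "crosses_full"):
        net = grow_network(build_pattern(kind, 2), seed=3)
        k.append(net.k_in.mean())
    assert k[0] > k[1] > k[2] > k[3]


def test_grow_network_deterministic(empty_pattern, small_config):
    a = grow_network(empty_pattern, small_config, seed=42)
    b = grow_network(empty_pattern, small_config, seed=42)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.dendrite_radii, b.dendrite_radii)
    assert (a.adjacency != b.adjacency).nnz == 0
    for ax_a, ax_b in zip(a.axons, b.axons):
        assert np.array_equal(ax_a, ax_b)
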