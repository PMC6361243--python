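"""Sliding-window, Voronoi-neighbourhood and pairwise environments."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairsite.environments import (
    NeighborGraph,
    env_onehot,
    env_real,
    pairwise_env,
    pairwise_env_features,
    sliding_window,
    voronoi_neighbors,
)
from pairsite.errors import ShapeMismatchError
from pairsite.structures import Residue


def delaunay_edges_bruteforce(points: np.ndarray) -> set[tuple[int, int]]:
    """Independent empty-circumsphere test over all 4-point subsets."""
    n = len(points)
    edges: set[tuple[int, int]] = set()
    for quad in itertools.combinations(range(n), 4):
        p = points[list(quad)]
        a = 2.0 * (p[1:] - p[0])
        b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
        try:
            center = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            continue
        r2 = ((p[0] - center) ** 2).sum()
        d2 = ((points - center) ** 2).sum(axis=1)
        others = [k for k in range(n) if k not in quad]
        if np.all(d2[others] >= r2 * (1 - 1e-9)):
            for e in itertools.combinations(quad, 2):
                edges.add((min(e), max(e)))
    return edges


def _ca_chain(coords):
    return [
        Residue("A", k, k + 1, "A", ["CA"],
                np.asarray([c], dtype=float), ["C"])
        for k, c in enumerate(coords)
    ]


class TestSlidingWindow:
    def test_center_of_length11_chain_concatenates_all(self):
        feats = np.arange(33).reshape(11, 3).astype(float)
        out = sliding_window(feats, 11)
        assert np.array_equal(out[5], feats.ravel())

    def test_first_residue_padded(self):
        feats = np.ones((11, 3))
        pad = np.array([9.0, 9.0, 9.0])
        out = sliding_window(feats, 11, pad)
        assert np.array_equal(out[0][:15], np.tile(pad, 5))
        assert np.array_equal(out[0][15:], np.ones(18))

    def test_constant_output_width(self):
        feats = np.random.default_rng(0).normal(size=(7, 4))
        out = sliding_window(feats, 11)
        assert out.shape == (7, 44)


class TestVoronoiNeighbors:
    def test_tetrahedron_is_complete(self):
        coords = [(0, 0, 0), (1, 0, 0), (0.5, np.sqrt(3) / 2, 0),
                  (0.5, np.sqrt(3) / 6, np.sqrt(2 / 3))]
        graph = voronoi_neighbors(_ca_chain(coords))
        assert len(graph.edges) == 6

    def test_matches_empty_circumsphere_oracle(self, rng):
        for _ in range(5):
            pts = rng.normal(scale=5, size=(12, 3))
            graph = voronoi_neighbors(_ca_chain(pts))
            assert graph.edges == delaunay_edges_bruteforce(pts)

    def test_missing_ca_is_neighborless(self, rng):
        chain = _ca_chain(rng.normal(scale=5, size=(8, 3)))
        chain[3] = Residue("A", 3, 4, "A")  # no atoms
        graph = voronoi_neighbors(chain)
        assert 3 in graph.neighborless
        assert graph.neighbors(3) == []

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(scale=5, size=(15, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = pts @ rot.T + np.array([10.0, -3.0, 2.0])
        assert voronoi_neighbors(_ca_chain(pts)).edges == \
            voronoi_neighbors(_ca_chain(moved)).edges

    def test_coplanar_points_jittered_not_crashed(self):
        pts = np.column_stack([np.arange(9.0) % 3, np.arange(9.0) // 3,
                               np.zeros(9)])
        graph = voronoi_neighbors(_ca_chain(pts))
        assert len(graph.edges) > 0


class TestEnvAggregations:
    def test_env_real_examples(self):
        env = env_real([2.0, 4.0])
        assert (env.sum, env.mean, env.max, env.min) == (6.0, 3.0, 4.0, 2.0)
        env1 = env_real([5.0])
        assert (env1.sum, env1.mean, env1.max, env1.min) == (5.0,) * 4

    def test_env_real_empty_flagged(self):
        env = env_real([])
        assert env.missing and env.as_array().tolist() == [0, 0, 0, 0]

    def test_env_onehot_sums_elementwise(self):
        out = env_onehot([[1, 0, 0], [0, 1, 0], [1, 0, 0]])
        assert out.tolist() == [2, 1, 0]
        assert out.sum() == 3  # one count per neighbour

    def test_env_onehot_length_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            env_onehot([[1, 0], [1, 0, 0]])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6,
                              allow_nan=False), min_size=1, max_size=30))
    def test_env_real_ordering_invariant(self, values):
        env = env_real(values)
        assert env.min <= env.mean + 1e-9 and env.mean <= env.max + 1e-9
        assert env.sum == pytest.approx(env.mean * len(values), rel=1e-9)


def _graph(n, edges):
    return NeighborGraph("A", n, {(min(a, b), max(a, b)) for a, b in edges})


class TestPairwiseEnv:
    def test_dot_j_example(self):
        f = np.zeros((3, 2))
        f[1, 0], f[2, 0] = 0.2, 0.6
        graph_a = _graph(3, [(0, 1), (0, 2)])
        graph_b = _graph(2, [])
        env = pairwise_env(f, 0, 0, graph_a, graph_b)
        assert env.env_dot_j.as_array() == pytest.approx([0.8, 0.4, 0.6, 0.2])
        assert env.env_i_dot.missing and env.env_dot_dot.missing

    def test_dot_dot_example(self):
        f = np.zeros((2, 3))
        f[1, 1], f[1, 2] = 0.1, 0.3
        graph_a = _graph(2, [(0, 1)])
        graph_b = _graph(3, [(0, 1), (0, 2)])
        env = pairwise_env(f, 0, 0, graph_a, graph_b)
        assert env.env_dot_dot.as_array() == pytest.approx([0.4, 0.2, 0.3, 0.1])

    def test_matches_bruteforce_and_batch(self, rng):
        f = rng.random((6, 6))
        edges_a = [(i, j) for i in range(6) for j in range(i + 1, 6)
                   if rng.random() < 0.4]
        edges_b = [(i, j) for i in range(6) for j in range(i + 1, 6)
                   if rng.random() < 0.4]
        ga, gb = _graph(6, edges_a), _graph(6, edges_b)
        batch = pairwise_env_features(f, ga, gb)
        for i in range(6):
            for j in range(6):
                env = pairwise_env(f, i, j, ga, gb)
                ni, nj = ga.neighbors(i), gb.neighbors(j)
                # independent nested-loop oracle
                if ni:
                    vals = [f[r, j] for r in ni]
                    assert env.env_dot_j.as_array() == pytest.approx(
                        [sum(vals), np.mean(vals), max(vals), min(vals)])
                if nj:
                    vals = [f[i, s] for s in nj]
                    assert env.env_i_dot.as_array() == pytest.approx(
                        [sum(vals), np.mean(vals), max(vals), min(vals)])
                if ni and nj:
                    vals = [f[r, s] for r in ni for s in nj]
                    assert env.env_dot_dot.as_array() == pytest.approx(
                        [sum(vals), sum(vals) / (len(ni) * len(nj)),
                         max(vals), min(vals)])
                assert batch[i, j] == pytest.approx(env.as_array())

    def test_transposition_swaps_dotj_and_idot(self, rng):
        f = rng.random((5, 4))
        ga = _graph(5, [(0, 1), (1, 2), (3, 4)])
        gb = _graph(4, [(0, 2), (1, 3)])
        env = pairwise_env(f, 1, 2, ga, gb)
        env_t = pairwise_env(f.T, 2, 1, gb, ga)
        assert env_t.env_dot_j.as_array() == pytest.approx(
            env.env_i_dot.as_array())
        assert env_t.env_i_dot.as_array() == pytest.approx(
            env.env_dot_j.as_array())
        assert env_t.env_dot_dot.as_array() == pytest.approx(
            env.env_dot_dot.as_array())

    def test_constant_matrix(self):
        f = np.full((4, 4), 0.3)
        ga = _graph(4, [(0, 1), (0, 2), (0, 3)])
        gb = _graph(4, [(0, 1)])
        env = pairwise_env(f, 0, 0, ga, gb)
        assert env.env_dot_j.as_array() == pytest.approx(
            [0.3 * 3, 0.3, 0.3, 0.3])
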