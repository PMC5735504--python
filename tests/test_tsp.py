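import itertools

import numpy as np
import pytest

from tsplink.errors import ParameterError, SizeError
from tsplink.tsp import (
    build_weight_matrix,
    path_cost,
    solve_exact_small,
    solve_heuristic,
    write_tsplib,
)

from conftest import rf_from_matrix


def brute_force_path(weights):
    """Minimum Hamiltonian path by exhaustive permutation enumeration."""
    n = len(weights)
    best = None
    best_cost = None
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:
            continue  # reversal has equal cost
        cost = sum(weights[perm[i], perm[i + 1]] for i in range(n - 1))
        if best_cost is None or cost < best_cost:
            best, best_cost = perm, cost
    return best, best_cost


def random_weight_matrix(n, rng, scale=1000):
    w = rng.integers(1, scale, size=(n + 1, n + 1))
    w = np.triu(w, 1)
    w = w + w.T
    w[n, :] = 0
    w[:, n] = 0
    return w


class TestBuild:
    def test_scaling(self):
        r = rf_from_matrix([[0, 0.25], [0.25, 0]])
        w = build_weight_matrix(r, [0, 1], scale=100000)
        assert w.weights[0, 1] == 25000

    def test_dummy_row_zero(self):
        r = rf_from_matrix(np.full((3, 3), 0.2) - 0.2 * np.eye(3))
        w = build_weight_matrix(r, [0, 1, 2])
        assert np.all(w.weights[w.dummy_index] == 0)
        assert np.all(w.weights[:, w.dummy_index] == 0)

    def test_singleton_subset(self):
        r = rf_from_matrix([[0, 0.1], [0.1, 0]])
        w = build_weight_matrix(r, [1])
        assert w.size == 2 and np.all(w.weights == 0)

    def test_duplicate_subset_rejected(self):
        r = rf_from_matrix([[0, 0.1], [0.1, 0]])
        with pytest.raises(ParameterError):
            build_weight_matrix(r, [0, 0])


class TestExact:
    def test_four_marker_instance(self):
        # pairwise distances with unique optimum path 0-1-2-3 of cost 6
        r = rf_from_matrix(np.zeros((4, 4)))
        w = build_weight_matrix(r, [0, 1, 2, 3], scale=1)
        dist = {(0, 1): 1, (0, 2): 4, (0, 3): 6, (1, 2): 2, (1, 3): 5, (2, 3): 3}
        for (i, j), v in dist.items():
            w.weights[i, j] = w.weights[j, i] = v
        p = solve_exact_small(w)
        assert p.order.tolist() == [0, 1, 2, 3]
        assert w.weights[:4, :4][p.order[:-1], p.order[1:]].sum() == 6

    def test_two_markers(self):
        r = rf_from_matrix([[0, 0.3], [0.3, 0]])
        p = solve_exact_small(build_weight_matrix(r, [0, 1]))
        assert p.cost == pytest.approx(0.3)

    def test_equal_weights_lexicographic(self):
        r = rf_from_matrix(np.full((5, 5), 0.2) - 0.2 * np.eye(5))
        p = solve_exact_small(build_weight_matrix(r, [0, 1, 2, 3, 4]))
        assert p.order.tolist() == [0, 1, 2, 3, 4]

    def test_size_limit(self):
        r = rf_from_matrix(np.zeros((20, 20)))
        with pytest.raises(SizeError, match="order_linkage_group"):
            solve_exact_small(build_weight_matrix(r, list(range(20))), limit=18)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        w = random_weight_matrix(n, rng)
        r = rf_from_matrix(np.zeros((n, n)))
        wm = build_weight_matrix(r, list(range(n)), scale=1)
        wm.weights[:, :] = w
        p = solve_exact_small(wm)
        _, best_cost = brute_force_path(w[:n, :n])
        got = w[:n, :n][p.order[:-1], p.order[1:]].sum()
        assert got == best_cost


class TestHeuristic:
    def test_recovers_line(self, line_rf):
        w = build_weight_matrix(line_rf, list(range(8)))
        p = solve_heuristic(w, seed=0)
        assert p.order.tolist() in ([0, 1, 2, 3, 4, 5, 6, 7],
                                    [7, 6, 5, 4, 3, 2, 1, 0])

    def test_single_marker(self, line_rf):
        p = solve_heuristic(build_weight_matrix(line_rf, [3]), seed=0)
        assert p.order.tolist() == [3] and p.cost == 0.0

    def test_deterministic(self, line_rf):
        w = build_weight_matrix(line_rf, list(range(8)))
        p1 = solve_heuristic(w, seed=42, perturbations=5)
        p2 = solve_heuristic(w, seed=42, perturbations=5)
        assert p1.order.tolist() == p2.order.tolist()

    @pytest.mark.parametrize("seed", range(10))
    def test_never_beats_exact(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(3, 9))
        w = random_weight_matrix(n, rng)
        r = rf_from_matrix(np.zeros((n, n)))
        wm = build_weight_matrix(r, list(range(n)), scale=1)
        wm.weights[:, :] = w
        exact = solve_exact_small(wm)
        heur = solve_heuristic(wm, seed=seed, perturbations=10)
        markers = w[:n, :n]
        c_exact = markers[exact.order[:-1], exact.order[1:]].sum()
        c_heur = markers[heur.order[:-1], heur.order[1:]].sum()
        assert c_heur >= c_exact

    def test_closing_edge_never_paid(self):
        # a line where the end-to-end edge is enormous: the dummy must
        # absorb the tour closure, so the optimal open path is the line
        m = 6
        idx = np.arange(m)
        mat = 0.01 * np.abs(idx[:, None] - idx[None, :])
        mat[0, m - 1] = mat[m - 1, 0] = 0.5
        r = rf_from_matrix(mat)
        w = build_weight_matrix(r, list(range(m)))
        p = solve_heuristic(w, seed=0)
        assert p.order.tolist() in ([0, 1, 2, 3, 4, 5], [5, 4, 3, 2, 1, 0])
        assert p.cost == pytest.approx(0.05, abs=1e-9)  # closing 0.5 edge unpaid


class TestPathCost:
    def test_sum(self, line_rf):
        w = build_weight_matrix(line_rf, [0, 1, 2])
        p = solve_heuristic(w, seed=0)
        assert path_cost(p, line_rf) == pytest.approx(p.cost)

    def test_reversal_invariant(self, line_rf):
        w = build_weight_matrix(line_rf, list(range(8)))
        p = solve_heuristic(w, seed=0)
        assert path_cost(p.reversed(), line_rf) == pytest.approx(path_cost(p, line_rf))

    def test_single_marker_zero(self, line_rf):
        p = solve_heuristic(build_weight_matrix(line_rf, [2]), seed=0)
        assert path_cost(p, line_rf) == 0.0


def test_tsplib_writer(tmp_path):
    r = rf_from_matrix([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
    w = build_weight_matrix(r, [0, 1, 2], scale=10)
    f = tmp_path / "inst.tsp"
    write_tsplib(w, f)
    text = f.read_text()
    assert "DIMENSION: 4" in text and "FULL_MATRIX" in text
    rows = [l for l in text.splitlines()
            if l and l[0].isdigit() and "DIMENSION" not in l]
    assert rows[-1] == "0 0 0 0"  # dummy row
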