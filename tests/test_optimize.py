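"""Layout optimizer primitives: cost, delta-cost, local search, perturbation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netgrid.optimize import (
    MOORE,
    CostTrace,
    Placement,
    check_layout,
    cost,
    delta_cost,
    init_random,
    make_grid,
    neighborhood_test,
    optimize_layout,
    perturb,
)

from conftest import random_instance


def brute_force_local_min(coords, W, width, height) -> bool:
    """Certificate: no single vacant-Moore move lowers the full recomputed cost."""
    base = cost(coords, W)
    occupied = {tuple(c) for c in coords}
    for i in range(len(coords)):
        for dx, dy in MOORE:
            cx, cy = coords[i, 0] + dx, coords[i, 1] + dy
            if not (0 <= cx < width and 0 <= cy < height):
                continue
            if (cx, cy) in occupied:
                continue
            trial = coords.copy()
            trial[i] = (cx, cy)
            if cost(trial, W) < base:
                return False
    return True


class TestGridAndInit:
    @pytest.mark.parametrize(
        "n, occ, expected", [(4, 0.25, (4, 4)), (1, 1.0, (1, 1)), (290, 0.25, (35, 35))]
    )
    def test_make_grid_formula(self, n, occ, expected):
        assert make_grid(n, occ) == expected

    def test_make_grid_holds_nodes(self):
        for n in (1, 7, 33, 100):
            w, h = make_grid(n, 0.9)
            assert w * h >= n

    def test_init_deterministic_and_valid(self):
        a = init_random(10, 7, 7, np.random.default_rng(42))
        b = init_random(10, 7, 7, np.random.default_rng(42))
        assert (a == b).all()
        check_layout(a, 7, 7)

    def test_init_full_grid(self):
        coords = init_random(9, 3, 3, np.random.default_rng(0))
        assert {tuple(c) for c in coords} == {(x, y) for x in range(3) for y in range(3)}

    def test_init_too_small_grid_raises(self):
        with pytest.raises(ValueError, match="cannot hold"):
            init_random(5, 2, 2, np.random.default_rng(0))

    def test_init_uniform_over_cells(self):
        """Single node on a 2x2 grid: each cell frequency within 3 sigma of 1/4."""
        rng = np.random.default_rng(123)
        draws = 10_000
        counts = np.zeros(4)
        for _ in range(draws):
            (x, y), = init_random(1, 2, 2, rng)
            counts[2 * x + y] += 1
        sigma = np.sqrt(draws * 0.25 * 0.75)
        assert (np.abs(counts - draws / 4) < 3 * sigma).all()


class TestCost:
    def test_direct_evaluation(self):
        W = np.array([[0, 3], [3, 0]])
        coords = np.array([[0, 0], [2, 1]])
        assert cost(coords, W) == 9

    def test_single_node_zero(self):
        assert cost(np.array([[5, 5]]), np.zeros((1, 1), dtype=int)) == 0

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        W, coords, *_ = random_instance(rng, 12)
        assert cost(coords, W) == cost(coords + np.array([1, 1]), W)


class TestDeltaCost:
    def test_matches_full_recompute_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 25))
            W, coords, width, height = random_instance(rng, n)
            i = int(rng.integers(n))
            occupied = {tuple(c) for c in coords}
            vacant = [(x, y) for x in range(width) for y in range(height)
                      if (x, y) not in occupied]
            target = vacant[int(rng.integers(len(vacant)))]
            trial = coords.copy()
            trial[i] = target
            assert delta_cost(coords, W, i, target, width, height) == (
                cost(trial, W) - cost(coords, W)
            )

    def test_zero_weight_node_free_to_move(self):
        rng = np.random.default_rng(2)
        W, coords, width, height = random_instance(rng, 6)
        W[0, :] = W[:, 0] = 0
        occupied = {tuple(c) for c in coords}
        target = next((x, y) for x in range(width) for y in range(height)
                      if (x, y) not in occupied)
        assert delta_cost(coords, W, 0, target, width, height) == 0

    def test_move_back_negates(self):
        rng = np.random.default_rng(3)
        W, coords, width, height = random_instance(rng, 8)
        origin = tuple(coords[2])
        target = (width - 1, height - 1)
        d1 = delta_cost(coords, W, 2, target, width, height)
        moved = coords.copy()
        moved[2] = target
        assert delta_cost(moved, W, 2, origin, width, height) == -d1

    def test_occupied_or_offgrid_target_rejected(self):
        rng = np.random.default_rng(4)
        W, coords, width, height = random_instance(rng, 5)
        with pytest.raises(ValueError, match="occupied"):
            delta_cost(coords, W, 0, tuple(coords[1]), width, height)
        with pytest.raises(ValueError, match="off-grid"):
            delta_cost(coords, W, 0, (width, 0), width, height)


class TestNeighborhoodTest:
    def test_local_minimum_is_fixed_point(self):
        rng = np.random.default_rng(5)
        W, coords, width, height = random_instance(rng, 15)
        first = neighborhood_test(coords, W, width, height)
        again = neighborhood_test(first, W, width, height)
        assert (first == again).all()

    def test_attractive_pair_ends_adjacent(self):
        # d = 1 uniquely minimizes 5*d over vacant-move-reachable layouts
        W = np.array([[0, 5], [5, 0]])
        coords = np.array([[0, 0], [3, 3]])
        out = neighborhood_test(coords, W, 4, 4)
        assert np.abs(out[0] - out[1]).sum() == 1

    def test_never_increases_cost_and_certificate(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            W, coords, width, height = random_instance(rng, n)
            out = neighborhood_test(coords, W, width, height)
            assert cost(out, W) <= cost(coords, W)
            check_layout(out, width, height)
            assert brute_force_local_min(out, W, width, height)

    def test_counts_evaluations(self):
        rng = np.random.default_rng(8)
        W, coords, width, height = random_instance(rng, 10)
        trace = CostTrace()
        neighborhood_test(coords, W, width, height, trace=trace)
        assert trace.n_evaluations > 0


class TestPerturb:
    def test_p_zero_is_identity(self):
        rng = np.random.default_rng(9)
        W, coords, width, height = random_instance(rng, 12)
        out = perturb(coords, 0.0, np.random.default_rng(0), width, height)
        assert (out == coords).all()

    def test_p_one_moves_every_node_with_vacancy(self):
        # widely separated nodes: every Moore neighborhood stays vacant
        coords = np.array([[0, 0], [5, 0], [0, 5], [5, 5]])
        out = perturb(coords, 1.0, np.random.default_rng(1), 10, 10)
        assert (out != coords).any(axis=1).all()
        check_layout(out, 10, 10)

    def test_saturated_grid_leaves_nodes_in_place(self):
        coords = np.array([[x, y] for x in range(2) for y in range(2)])
        out = perturb(coords, 1.0, np.random.default_rng(2), 2, 2)
        assert (out == coords).all()

    @given(st.integers(0, 2**31 - 1), st.floats(0, 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariants_preserved(self, seed, p):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        W, coords, width, height = random_instance(rng, n)
        out = perturb(coords, p, rng, width, height)
        check_layout(out, width, height)


class TestOptimizeLayout:
    def test_seeded_runs_bit_identical(self):
        rng = np.random.default_rng(11)
        W, _, width, height = random_instance(rng, 20)
        a, ta = optimize_layout(W, width, height, n_iter=10,
                                rng=np.random.default_rng(5))
        b, tb = optimize_layout(W, width, height, n_iter=10,
                                rng=np.random.default_rng(5))
        assert (a == b).all()
        assert ta.accepted_costs == tb.accepted_costs

    def test_trace_monotone_and_complete(self):
        rng = np.random.default_rng(12)
        W, _, width, height = random_instance(rng, 25)
        _, trace = optimize_layout(W, width, height, n_iter=15,
                                   rng=np.random.default_rng(0))
        costs = trace.accepted_costs
        assert len(costs) == 16
        assert all(a >= b for a, b in zip(costs, costs[1:]))

    def test_p_zero_keeps_converged_layout(self):
        rng = np.random.default_rng(13)
        W, _, width, height = random_instance(rng, 15)
        coords, trace = optimize_layout(W, width, height, p=0.0, n_iter=8,
                                        rng=np.random.default_rng(3))
        assert len(set(trace.accepted_costs)) == 1

    def test_triangle_reaches_enumerated_optimum(self):
        """All-attractive triangle on a 2x2 grid hits the brute-force minimum."""
        W = np.full((3, 3), 6)
        np.fill_diagonal(W, 0)
        cells = [(x, y) for x in range(2) for y in range(2)]
        brute = min(cost(np.array(perm), W)
                    for perm in itertools.permutations(cells, 3))
        coords, trace = optimize_layout(W, 2, 2, n_iter=20,
                                        rng=np.random.default_rng(7))
        assert trace.accepted_costs[-1] == brute == cost(coords, W)


class TestPlacement:
    def test_rejects_shared_cell(self):
        with pytest.raises(ValueError, match="share"):
            Placement(["a", "b"], np.array([[0, 0], [0, 0]]), 3, 3)

    def test_bounding_box_area(self):
        p = Placement(["a", "b"], np.array([[1, 1], [3, 2]]), 5, 5)
        assert p.bounding_box_area() == 6

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariants_through_operation_sequences(self, seed):
        """Random perturb/neighborhood-test chains keep layouts valid."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 25))
        W, coords, width, height = random_instance(rng, n)
        for _ in range(4):
            if rng.random() < 0.5:
                coords = perturb(coords, rng.random(), rng, width, height)
            else:
                coords = neighborhood_test(coords, W, width, height)
            check_layout(coords, width, height)
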