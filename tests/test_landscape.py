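"""Landscape enumeration, minima, basins, barriers, disconnectivity trees.

The oracle for the minimax barrier is threshold connectivity, computed with
a plain BFS: the barrier between a and b is the smallest energy level E such
that a and b are connected within the sub-hypercube of states whose energy
is <= E.  This is independent of both the Dijkstra variant and the
union-find sweep it checks.
"""

import itertools

import numpy as np
import pytest

from energylandscape import (
    MEMParams,
    assign_basins,
    boltzmann_distribution,
    build_disconnectivity_tree,
    build_landscape,
    decode_state,
    encode_state,
    energy,
    enumerate_energies,
    find_local_minima,
    minimax_barrier,
)
from conftest import random_params


def brute_force_minima(energies, n):
    out = []
    for s in range(len(energies)):
        if all(energies[s] < energies[s ^ (1 << k)] for k in range(n)):
            out.append(s + 1)
    return out


def bfs_barrier(energies, n, a, b):
    """Threshold-connectivity oracle (independent of Dijkstra)."""
    levels = sorted(set(energies))
    for level in levels:
        if level < max(energies[a - 1], energies[b - 1]):
            continue
        allowed = {s for s in range(len(energies)) if energies[s] <= level}
        frontier, seen = [a - 1], {a - 1}
        while frontier:
            u = frontier.pop()
            if u == b - 1:
                return level
            for k in range(n):
                v = u ^ (1 << k)
                if v in allowed and v not in seen:
                    seen.add(v)
                    frontier.append(v)
    raise AssertionError("hypercube is connected")


class TestEnumerateEnergies:
    def test_zero_params_flat(self):
        params = MEMParams(h=np.zeros(3), J=np.zeros((3, 3)))
        assert enumerate_energies(params) == pytest.approx(np.zeros(8))

    def test_two_region_hand_derived(self):
        # E = -(h1 s1 + h2 s2) - J12 s1 s2 at states (-1,-1),(-1,+1),(+1,-1),(+1,+1)
        params = MEMParams(h=[1.0, -1.0], J=[[0.0, 0.5], [0.5, 0.0]])
        assert enumerate_energies(params) == pytest.approx([-0.5, 2.5, -1.5, -0.5])

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_per_state_energy(self, trial):
        rng = np.random.default_rng(200 + trial)
        params = random_params(5, rng)
        energies = enumerate_energies(params)
        for s in range(1, 33):
            assert energies[s - 1] == pytest.approx(
                energy(decode_state(s, 5), params)
            )


class TestLocalMinima:
    def test_ferromagnet_has_two_minima(self):
        J = 0.5 * (np.ones((3, 3)) - np.eye(3))
        scape = build_landscape(MEMParams(h=np.zeros(3), J=J))
        assert scape.local_minima == (1, 8)  # all-inactive and all-active
        assert scape.energies[0] == scape.energies[7]

    def test_factorized_model_single_sign_h_minimum(self):
        params = MEMParams(h=[1.0, -2.0, 3.0], J=np.zeros((3, 3)))
        minima = find_local_minima(enumerate_energies(params), 3)
        assert minima == [encode_state([1, -1, 1])]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(300 + trial)
        energies = rng.normal(size=16)
        assert find_local_minima(energies, 4) == brute_force_minima(energies, 4)

    def test_plateau_is_not_a_minimum(self):
        energies = np.zeros(4)  # every neighbor ties
        assert find_local_minima(energies, 2) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            find_local_minima(np.zeros(7), 3)


class TestBasins:
    def test_minima_are_fixed_points(self, rng):
        energies = rng.normal(size=16)
        basins = assign_basins(energies, 4)
        for s in find_local_minima(energies, 4):
            assert basins[s - 1] == s

    def test_ferromagnet_majority_descends_to_matching_pole(self):
        J = 0.5 * (np.ones((3, 3)) - np.eye(3))
        scape = build_landscape(MEMParams(h=np.zeros(3), J=J))
        for s in range(1, 9):
            pattern = decode_state(s, 3)
            if pattern.sum() > 0:
                assert scape.basin_of[s - 1] == 8
            elif pattern.sum() < 0:
                assert scape.basin_of[s - 1] == 1

    @pytest.mark.parametrize("trial", range(10))
    def test_basin_image_is_the_minima_set(self, trial):
        rng = np.random.default_rng(400 + trial)
        energies = rng.normal(size=16)
        basins = assign_basins(energies, 4)
        assert set(basins) == set(find_local_minima(energies, 4))

    def test_steepest_descent_ties_resolve_to_lowest_index(self):
        # state 4 = (+1,+1): both neighbors (states 2 and 3) tie at energy -1
        energies = np.array([0.0, -1.0, -1.0, 0.5])
        basins = assign_basins(energies, 2)
        assert basins[3] == 2


class TestMinimaxBarrier:
    def test_degenerate_path(self, rng):
        energies = rng.normal(size=8)
        assert minimax_barrier(energies, 3, 5, 5) == pytest.approx(energies[4])

    def test_two_region_square(self):
        energies = np.array([-2.0, 1.0, 0.5, -2.0])
        # two 2-step paths around the square: max 1.0 via state 2, 0.5 via state 3
        assert minimax_barrier(energies, 2, 1, 4) == pytest.approx(0.5)

    @pytest.mark.parametrize("trial", range(5))
    def test_symmetry(self, trial):
        rng = np.random.default_rng(500 + trial)
        energies = rng.normal(size=16)
        for a, b in [(1, 16), (3, 9), (5, 12)]:
            assert minimax_barrier(energies, 4, a, b) == pytest.approx(
                minimax_barrier(energies, 4, b, a)
            )

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_threshold_connectivity_oracle(self, trial):
        rng = np.random.default_rng(600 + trial)
        energies = rng.normal(size=16)
        for a, b in itertools.combinations(range(1, 17), 2):
            assert minimax_barrier(energies, 4, a, b) == pytest.approx(
                bfs_barrier(energies, 4, a, b)
            )


class TestDisconnectivityTree:
    def test_single_minimum_single_leaf(self):
        params = MEMParams(h=[1.0, -2.0, 3.0], J=np.zeros((3, 3)))
        tree = build_disconnectivity_tree(build_landscape(params))
        assert len(tree.nodes) == 1
        assert tree.nodes[tree.root].is_leaf

    def test_two_minima_merge_at_hand_computed_barrier(self):
        # h=(0.25, 0), J12=2 gives energies (-1.75, 2.25, 1.75, -2.25):
        # minima at states 1 and 4, lowest saddle through state 3 at 1.75
        params = MEMParams(h=[0.25, 0.0], J=[[0.0, 2.0], [2.0, 0.0]])
        energies = enumerate_energies(params)
        assert energies == pytest.approx([-1.75, 2.25, 1.75, -2.25])
        tree = build_disconnectivity_tree(build_landscape(params))
        assert sorted(leaf.state for leaf in tree.leaves) == [1, 4]
        assert tree.nodes[tree.root].height == pytest.approx(1.75)
        assert tree.barrier_between(1, 4) == pytest.approx(1.75)

    @pytest.mark.parametrize("trial", range(10))
    def test_lca_heights_equal_dijkstra_barriers(self, trial):
        rng = np.random.default_rng(700 + trial)
        params = random_params(4, rng, scale=1.0)
        scape = build_landscape(params)
        tree = build_disconnectivity_tree(scape)
        assert sorted(leaf.state for leaf in tree.leaves) == list(scape.local_minima)
        for a, b in itertools.combinations(scape.local_minima, 2):
            assert tree.barrier_between(a, b) == pytest.approx(
                minimax_barrier(scape.energies, 4, a, b)
            )

    @pytest.mark.parametrize("trial", range(10))
    def test_ultrametric_inequality(self, trial):
        rng = np.random.default_rng(800 + trial)
        scape = build_landscape(random_params(4, rng, scale=1.0))
        tree = build_disconnectivity_tree(scape)
        for a, b, c in itertools.combinations(scape.local_minima, 3):
            assert tree.barrier_between(a, c) <= max(
                tree.barrier_between(a, b), tree.barrier_between(b, c)
            ) + 1e-12

    def test_barriers_dominate_leaf_energies(self, rng):
        scape = build_landscape(random_params(5, rng, scale=1.0))
        tree = build_disconnectivity_tree(scape)
        for node in tree.nodes:
            if node.parent is not None:
                assert tree.nodes[node.parent].height >= node.height - 1e-12

    def test_flip_symmetric_minima_without_bias(self, rng):
        params = random_params(5, rng, scale=0.8)
        params = MEMParams(h=np.zeros(5), J=params.J)
        scape = build_landscape(params)
        flipped = {32 + 1 - s for s in scape.local_minima}  # global sign flip
        assert flipped == set(scape.local_minima)
        for s in scape.local_minima:
            assert scape.energies[s - 1] == pytest.approx(
                scape.energies[32 - s], abs=1e-12
            )

    def test_global_minimum_is_boltzmann_mode(self, rng):
        params = random_params(5, rng)
        scape = build_landscape(params)
        probs = boltzmann_distribution(params)
        assert np.argmin(scape.energies) == np.argmax(probs)

    def test_newick_and_text_exports(self):
        params = MEMParams(h=[0.25, 0.0], J=[[0.0, 2.0], [2.0, 0.0]])
        tree = build_disconnectivity_tree(build_landscape(params))
        newick = tree.to_newick()
        assert newick.endswith(";") and "S1" in newick and "S4" in newick
        text = tree.to_text()
        assert "state 1" in text and "barrier 1.75" in text
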