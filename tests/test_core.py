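"""State encoding, energy function, Boltzmann distribution, empirical stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from energylandscape import (
    BinaryPatternSeries,
    CapacityError,
    InvalidPatternError,
    MEMParams,
    all_patterns,
    boltzmann_distribution,
    decode_state,
    empirical_stats,
    encode_state,
    energy,
)
from conftest import random_params


class TestStateEncoding:
    @pytest.mark.parametrize(
        "pattern,index",
        [
            ([-1] * 10, 1),        # all-inactive is state 1
            ([1] * 10, 1024),      # all-active is state 2^N
            ([1, -1], 3),          # ROI 1 is the most significant bit
            ([-1, 1], 2),
            ([-1], 1),
            ([1], 2),
        ],
    )
    def test_encode_examples(self, pattern, index):
        assert encode_state(pattern) == index

    @pytest.mark.parametrize(
        "index,n,pattern",
        [(1, 3, [-1, -1, -1]), (8, 3, [1, 1, 1]), (3, 2, [1, -1])],
    )
    def test_decode_examples(self, index, n, pattern):
        assert decode_state(index, n).tolist() == pattern

    @pytest.mark.parametrize("n", range(1, 9))
    def test_roundtrip_bijection(self, n):
        indices = [encode_state(decode_state(s, n)) for s in range(1, 2**n + 1)]
        assert indices == list(range(1, 2**n + 1))

    def test_all_patterns_rows_match_decode(self):
        pats = all_patterns(4)
        for s in range(1, 17):
            assert np.array_equal(pats[s - 1], decode_state(s, 4))

    def test_invalid_pattern_rejected(self):
        with pytest.raises(InvalidPatternError):
            encode_state([1, 0, -1])

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            decode_state(9, 3)
        with pytest.raises(ValueError):
            decode_state(0, 3)

    def test_capacity_guard(self):
        with pytest.raises(CapacityError):
            all_patterns(21)


class TestEnergy:
    def test_two_region_example(self):
        params = MEMParams(h=[1.0, -1.0], J=[[0.0, 0.5], [0.5, 0.0]])
        assert energy([1, 1], params) == pytest.approx(-0.5)

    def test_zero_params_zero_energy(self, rng):
        params = MEMParams(h=np.zeros(5), J=np.zeros((5, 5)))
        assert energy(rng.choice([-1, 1], 5), params) == 0.0

    def test_three_region_uniform_coupling(self):
        J = np.ones((3, 3)) - np.eye(3)
        params = MEMParams(h=np.zeros(3), J=J)
        # each of the 3 unordered pairs contributes J*sigma*sigma = 1 once
        assert energy([1, 1, 1], params) == pytest.approx(-3.0)

    def test_dimension_mismatch(self):
        params = MEMParams(h=np.zeros(3), J=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            energy([1, 1], params)

    @pytest.mark.parametrize("trial", range(10))
    def test_flip_symmetry_without_bias(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 7))
        params = random_params(n, rng)
        params = MEMParams(h=np.zeros(n), J=params.J)
        sigma = rng.choice([-1, 1], n)
        assert energy(sigma, params) == energy(-sigma, params)

    def test_asymmetric_J_rejected(self):
        with pytest.raises(ValueError):
            MEMParams(h=[0.0, 0.0], J=[[0.0, 0.3], [0.2, 0.0]])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            MEMParams(h=[0.0, 0.0], J=[[0.1, 0.0], [0.0, 0.0]])


class TestBoltzmann:
    def test_single_region_symmetric(self):
        params = MEMParams(h=[0.0], J=[[0.0]])
        assert boltzmann_distribution(params) == pytest.approx([0.5, 0.5])

    def test_single_region_closed_form(self):
        # P(+1) = e^h / (e^h + e^-h)
        params = MEMParams(h=[0.5], J=[[0.0]])
        probs = boltzmann_distribution(params)
        assert probs[1] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_normalization(self, trial):
        rng = np.random.default_rng(100 + trial)
        params = random_params(4, rng, scale=2.0)
        assert boltzmann_distribution(params).sum() == pytest.approx(1.0, abs=1e-12)

    def test_probability_ranks_follow_negative_energy(self, rng):
        from energylandscape import enumerate_energies

        params = random_params(5, rng)
        probs = boltzmann_distribution(params)
        energies = enumerate_energies(params)
        assert np.array_equal(np.argsort(-probs), np.argsort(energies, kind="stable"))


class TestEmpiricalStats:
    def test_single_time_point(self):
        series = BinaryPatternSeries(data=[[1], [-1]], roi_names=["a", "b"])
        stats = empirical_stats(series)
        assert stats.mean_activity.tolist() == [1.0, -1.0]
        assert stats.frequencies == {encode_state([1, -1]): 1.0}

    def test_alternating_series_perfectly_correlated(self):
        data = np.array([[1, -1, 1, -1], [1, -1, 1, -1], [1, -1, 1, -1]])
        stats = empirical_stats(BinaryPatternSeries(data=data, roi_names="abc"))
        assert stats.mean_activity == pytest.approx([0.0, 0.0, 0.0])
        assert stats.pairwise_products == pytest.approx(np.ones((3, 3)))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_frequencies_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n, t = int(rng.integers(1, 6)), int(rng.integers(1, 50))
        data = rng.choice([-1, 1], size=(n, t))
        stats = empirical_stats(
            BinaryPatternSeries(data=data, roi_names=[f"r{i}" for i in range(n)])
        )
        assert sum(stats.frequencies.values()) == pytest.approx(1.0)
        assert np.all(np.abs(stats.mean_activity) <= 1.0)
        assert np.allclose(stats.pairwise_products, stats.pairwise_products.T)
        assert np.diagonal(stats.pairwise_products) == pytest.approx(1.0)

    def test_non_binary_series_rejected(self):
        with pytest.raises(InvalidPatternError):
            BinaryPatternSeries(data=[[1, 0]], roi_names=["a"])
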