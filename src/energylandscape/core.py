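"""Pairwise maximum-entropy (Ising) model core.

Binary activity patterns over ``N`` regions of interest (ROIs) live in
``{-1, +1}^N``; +1 marks an active region, -1 an inactive one.  The pairwise
maximum-entropy model (MEM) assigns each pattern an energy

    E(sigma | h, J) = - sum_i h_i sigma_i - 1/2 sum_i sum_{j != i} J_ij sigma_i sigma_j

with per-region biases ``h`` and symmetric, zero-diagonal couplings ``J``,
and a Boltzmann probability P(sigma) = exp(-E(sigma)) / Z at unit
temperature.  All operations here enumerate the full set of 2^N states, so
N is capped (the model is only ever fit to networks of at most ~12 ROIs).

State numbering is 1-based: ROI 1 is the most significant bit and -1 maps
to bit 0, so the all-inactive pattern is state 1 and the all-active pattern
is state 2^N (e.g. state 1024 for a 10-ROI network).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

#: Hard cap on the number of regions; every operation is exhaustive in 2^N.
MAX_REGIONS = 20


class CapacityError(ValueError):
    """Number of regions exceeds the exhaustive-enumeration capacity."""


class InvalidPatternError(ValueError):
    """A pattern contains entries other than -1 or +1."""


def _check_capacity(n_regions: int) -> None:
    if not 1 <= n_regions <= MAX_REGIONS:
        raise CapacityError(
            f"n_regions={n_regions} outside [1, {MAX_REGIONS}]; all operations "
            f"enumerate 2^N states"
        )


def _as_pattern(pattern) -> np.ndarray:
    arr = np.asarray(pattern)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidPatternError("pattern must be a non-empty 1-D vector")
    if not np.isin(arr, (-1, 1)).all():
        bad = arr[~np.isin(arr, (-1, 1))][0]
        raise InvalidPatternError(f"pattern entries must be -1 or +1, got {bad!r}")
    return arr.astype(np.int8)


@dataclass(frozen=True)
class BinaryPatternSeries:
    """A binarized multivariate time series: N regions x t_max time points.

    ``data[i, t]`` is sigma_i(t) in {-1, +1}.
    """

    data: np.ndarray
    roi_names: Tuple[str, ...]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("data must be a non-empty N x t_max matrix")
        if not np.isin(data, (-1, 1)).all():
            raise InvalidPatternError("series entries must be -1 or +1")
        names = tuple(str(x) for x in self.roi_names)
        if len(names) != data.shape[0]:
            raise ValueError(
                f"{len(names)} roi_names for {data.shape[0]} regions"
            )
        if len(set(names)) != len(names):
            raise ValueError("roi_names must be unique")
        object.__setattr__(self, "data", data.astype(np.int8))
        object.__setattr__(self, "roi_names", names)
        self.data.setflags(write=False)

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def t_max(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class MEMParams:
    """Pairwise MEM parameters: biases ``h`` (N,) and couplings ``J`` (N, N).

    ``J`` must be symmetric with an all-zero diagonal; each unordered pair
    {i, j} contributes J_ij sigma_i sigma_j to the energy exactly once.
    """

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.h, dtype=float)
        J = np.asarray(self.J, dtype=float)
        if h.ndim != 1:
            raise ValueError("h must be a 1-D vector")
        n = h.size
        _check_capacity(n)
        if J.shape != (n, n):
            raise ValueError(f"J must be {n}x{n}, got {J.shape}")
        if not np.isfinite(h).all() or not np.isfinite(J).all():
            raise ValueError("parameters must be finite")
        if not np.array_equal(J, J.T):
            raise ValueError("J must be symmetric")
        if np.diagonal(J).any():
            raise ValueError("diagonal of J must be zero")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "J", J)
        self.h.setflags(write=False)
        self.J.setflags(write=False)

    @property
    def n_regions(self) -> int:
        return self.h.size


@dataclass(frozen=True)
class EmpiricalStats:
    """Time-averaged first/second moments and state frequencies of a series."""

    mean_activity: np.ndarray          # <sigma_i>, length N
    pairwise_products: np.ndarray      # <sigma_i sigma_j>, N x N, unit diagonal
    frequencies: Dict[int, float]      # 1-based state index -> relative frequency


# --------------------------------------------------------------------------
# state encoding
# --------------------------------------------------------------------------

def encode_state(pattern) -> int:
    """Map a ±1 pattern to its 1-based state index.

    ROI 1 is the most significant bit (-1 -> 0, +1 -> 1), so the all-inactive
    pattern is state 1 and the all-active pattern is state 2^N.
    """
    arr = _as_pattern(pattern)
    n = arr.size
    _check_capacity(n)
    bits = (arr.astype(np.int64) + 1) // 2
    weights = np.int64(1) << np.arange(n - 1, -1, -1, dtype=np.int64)
    return int(bits @ weights) + 1


def decode_state(index: int, n_regions: int) -> np.ndarray:
    """Inverse of :func:`encode_state`; returns a ±1 vector of length N."""
    _check_capacity(n_regions)
    n_states = 1 << n_regions
    if not 1 <= index <= n_states:
        raise ValueError(f"state index {index} outside [1, {n_states}] for N={n_regions}")
    offset = index - 1
    bits = (offset >> np.arange(n_regions - 1, -1, -1)) & 1
    return (2 * bits - 1).astype(np.int8)


@lru_cache(maxsize=None)
def all_patterns(n_regions: int) -> np.ndarray:
    """The (2^N, N) matrix of all ±1 patterns, row s-1 = decode_state(s)."""
    _check_capacity(n_regions)
    offsets = np.arange(1 << n_regions, dtype=np.int64)
    bits = (offsets[:, None] >> np.arange(n_regions - 1, -1, -1)) & 1
    patterns = (2 * bits - 1).astype(np.int8)
    patterns.setflags(write=False)
    return patterns


def encode_series(series: BinaryPatternSeries) -> np.ndarray:
    """1-based state index of every time point of a series (length t_max)."""
    n = series.n_regions
    _check_capacity(n)
    bits = ((series.data.astype(np.int64) + 1) // 2)
    weights = np.int64(1) << np.arange(n - 1, -1, -1, dtype=np.int64)
    return weights @ bits + 1


# --------------------------------------------------------------------------
# energies and the Boltzmann distribution
# --------------------------------------------------------------------------

def energy(pattern, params: MEMParams) -> float:
    """E(sigma | h, J) for a single ±1 pattern."""
    arr = _as_pattern(pattern).astype(float)
    if arr.size != params.n_regions:
        raise ValueError(
            f"pattern length {arr.size} != model dimension {params.n_regions}"
        )
    return float(-(params.h @ arr) - 0.5 * arr @ params.J @ arr)


def pattern_energies(patterns: np.ndarray, params: MEMParams) -> np.ndarray:
    """Energies of a (S, N) stack of ±1 patterns, vectorized."""
    P = np.asarray(patterns, dtype=float)
    if P.ndim != 2 or P.shape[1] != params.n_regions:
        raise ValueError(
            f"pattern stack must be (S, {params.n_regions}), got {P.shape}"
        )
    return -(P @ params.h) - 0.5 * ((P @ params.J) * P).sum(axis=1)


def boltzmann_distribution(params: MEMParams) -> np.ndarray:
    """Probabilities of all 2^N states, indexed by state offset (index - 1)."""
    E = pattern_energies(all_patterns(params.n_regions), params)
    logZ = logsumexp(-E)
    return np.exp(-E - logZ)


# --------------------------------------------------------------------------
# empirical statistics
# --------------------------------------------------------------------------

def empirical_stats(series: BinaryPatternSeries) -> EmpiricalStats:
    """Time-averaged moments and state frequencies of a binarized series.

    mean_activity_i = (1/t_max) sum_t sigma_i(t); pairwise_products is the
    analogous second-moment matrix (unit diagonal); frequencies counts each
    observed state's occurrences divided by t_max.
    """
    data = series.data.astype(float)
    t_max = series.t_max
    m1 = data.mean(axis=1)
    m2 = (data @ data.T) / t_max
    np.fill_diagonal(m2, 1.0)
    codes, counts = np.unique(encode_series(series), return_counts=True)
    freqs = {int(c): cnt / t_max for c, cnt in zip(codes, counts)}
    return EmpiricalStats(mean_activity=m1, pairwise_products=m2, frequencies=freqs)
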