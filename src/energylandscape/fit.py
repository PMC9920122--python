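"""Maximum-likelihood fitting of the pairwise MEM by gradient ascent.

The i.i.d. likelihood L(h, J) = prod_t P(sigma(t) | h, J) is maximized by
moment-matching gradient ascent:

    h_i  <- h_i  + eps (<sigma_i>_emp        - <sigma_i>_model)
    J_ij <- J_ij + eps (<sigma_i sigma_j>_emp - <sigma_i sigma_j>_model)

iterated until the largest absolute moment mismatch falls below a tolerance.
The log-likelihood is concave in (h, J), so the stationary point is the
unique MLE and the mismatch doubles as the convergence oracle.  Model
moments are exact expectations over all 2^N states, recomputed each step,
which is what limits the method to small networks (N <= 12 in practice).

A step that decreases the log-likelihood is rejected and the learning rate
halved; non-convergence within the iteration budget is reported honestly in
the result rather than raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import logsumexp

from .core import (
    BinaryPatternSeries,
    EmpiricalStats,
    MEMParams,
    all_patterns,
    boltzmann_distribution,
    empirical_stats,
    pattern_energies,
)

logger = logging.getLogger(__name__)


class DivergenceError(ArithmeticError):
    """Parameters became non-finite; retry with a smaller learning rate."""


@dataclass(frozen=True)
class FitConfig:
    """Gradient-ascent settings.

    learning_rate: initial step size eps (halved whenever a step would
        decrease the log-likelihood).
    tolerance: convergence threshold on the max absolute mismatch between
        empirical and model first/second moments.
    max_iterations: iteration budget; exceeding it is reported, not raised.
    track_history: record the per-iteration log-likelihood trajectory.
    """

    learning_rate: float = 0.1
    tolerance: float = 1e-5
    max_iterations: int = 50_000
    track_history: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class FitResult:
    params: MEMParams
    converged: bool
    iterations: int
    final_mismatch: float
    log_likelihood: float
    halvings: int = 0
    history: Optional[List[float]] = None


def log_likelihood(series: BinaryPatternSeries, params: MEMParams) -> float:
    """sum_t log P(sigma(t) | h, J); always <= 0."""
    if series.n_regions != params.n_regions:
        raise ValueError(
            f"series has {series.n_regions} regions, params {params.n_regions}"
        )
    E_obs = pattern_energies(series.data.T, params)
    E_all = pattern_energies(all_patterns(params.n_regions), params)
    logZ = logsumexp(-E_all)
    return float(-(E_obs.sum()) - series.t_max * logZ)


def model_moments(params: MEMParams) -> Tuple[np.ndarray, np.ndarray]:
    """Exact <sigma_i> and <sigma_i sigma_j> under the Boltzmann distribution."""
    P = all_patterns(params.n_regions).astype(float)
    probs = boltzmann_distribution(params)
    m1 = probs @ P
    m2 = (P * probs[:, None]).T @ P
    np.fill_diagonal(m2, 1.0)
    return m1, m2


def _evaluate(P, h, J, emp1, emp2, t_max):
    """One sweep: probabilities, mean log-likelihood, gradients, mismatch."""
    E = -(P @ h) - 0.5 * ((P @ J) * P).sum(axis=1)
    logZ = logsumexp(-E)
    probs = np.exp(-E - logZ)
    # log L / t_max via the moment form: <sigma>_emp couples to h, pairs to J
    ll = t_max * (h @ emp1 + 0.5 * (J * emp2).sum() - logZ)
    m1 = probs @ P
    m2 = (P * probs[:, None]).T @ P
    g1 = emp1 - m1
    g2 = emp2 - m2
    np.fill_diagonal(g2, 0.0)
    mismatch = max(np.abs(g1).max(), np.abs(g2).max())
    return ll, g1, g2, mismatch


def fit_mle(series: BinaryPatternSeries, config: Optional[FitConfig] = None) -> FitResult:
    """Fit (h, J) to a binarized series by moment-matching gradient ascent.

    Initialization is h = 0, J = 0 (the uniform model); concavity makes the
    optimum unique, so initialization only affects speed.  Patterns absent
    from the data contribute only through the partition function.
    """
    config = config or FitConfig()
    stats = empirical_stats(series)
    return fit_mle_from_stats(stats, series.t_max, config)


def fit_mle_from_stats(
    stats: EmpiricalStats, t_max: int, config: Optional[FitConfig] = None
) -> FitResult:
    """As :func:`fit_mle` but starting from precomputed empirical moments."""
    config = config or FitConfig()
    emp1 = np.asarray(stats.mean_activity, dtype=float)
    emp2 = np.asarray(stats.pairwise_products, dtype=float)
    n = emp1.size
    P = all_patterns(n).astype(float)

    h = np.zeros(n)
    J = np.zeros((n, n))
    eps = config.learning_rate
    halvings = 0
    history: List[float] = []

    ll, g1, g2, mismatch = _evaluate(P, h, J, emp1, emp2, t_max)
    iterations = 0
    converged = mismatch <= config.tolerance
    if config.track_history:
        history.append(ll)

    while not converged and iterations < config.max_iterations:
        h_new = h + eps * g1
        J_new = J + eps * g2
        if not (np.isfinite(h_new).all() and np.isfinite(J_new).all()):
            raise DivergenceError(
                "parameters overflowed; retry with a smaller learning_rate"
            )
        ll_new, g1_new, g2_new, mismatch_new = _evaluate(
            P, h_new, J_new, emp1, emp2, t_max
        )
        iterations += 1
        if not np.isfinite(ll_new):
            raise DivergenceError(
                "log-likelihood overflowed; retry with a smaller learning_rate"
            )
        if ll_new < ll - 1e-12:
            # uphill guarantee: reject the step and halve the rate
            eps *= 0.5
            halvings += 1
            if eps == 0.0:
                break
            continue
        h, J, ll, g1, g2, mismatch = h_new, J_new, ll_new, g1_new, g2_new, mismatch_new
        if config.track_history:
            history.append(ll)
        if iterations % 5000 == 0:
            logger.info(
                "fit iteration %d: mismatch %.3g, log-likelihood %.6g",
                iterations, mismatch, ll,
            )
        converged = mismatch <= config.tolerance

    J = 0.5 * (J + J.T)  # exact symmetry against float drift
    np.fill_diagonal(J, 0.0)
    params = MEMParams(h=h, J=J)
    logger.debug(
        "fit finished: converged=%s after %d iterations, mismatch %.3g",
        converged, iterations, mismatch,
    )
    return FitResult(
        params=params,
        converged=bool(converged),
        iterations=iterations,
        final_mismatch=float(mismatch),
        log_likelihood=float(ll),
        halvings=halvings,
        history=history if config.track_history else None,
    )
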