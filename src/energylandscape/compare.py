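"""Connectivity-signature extraction: t-tests on per-subject state energies.

A candidate connectivity state (a local minimum of either group's energy
landscape) is scored per subject by fitting that subject's own pairwise MEM
and evaluating the state's energy under the subject's fitted parameters.
The two groups' energy samples are compared with a two-sample t-test, and
the family-wise error rate over all M tested minima (pooled over networks
and both groups, duplicates counted per group) is controlled by Bonferroni
correction: a state is a signature when p < alpha / M.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .core import BinaryPatternSeries, MEMParams, decode_state, energy
from .fit import FitConfig, FitResult, fit_mle


class DegenerateSampleError(ValueError):
    """A t-test sample is too small or has zero variance."""


class IncompleteInputError(ValueError):
    """A candidate state lacks energy samples for one of the groups."""


@dataclass(frozen=True)
class ComparisonConfig:
    """Family-wise significance level, t-test flavor, and comparison count M."""

    alpha: float = 0.05
    test_flavor: str = "pooled"     # "pooled" or "welch"
    m_comparisons: int = 1

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.test_flavor not in ("pooled", "welch"):
            raise ValueError("test_flavor must be 'pooled' or 'welch'")
        if self.m_comparisons < 1:
            raise ValueError("m_comparisons must be >= 1")


@dataclass(frozen=True)
class CandidateState:
    """One state to be tested, with per-group per-subject energy samples."""

    network: str
    state: int
    n_regions: int
    group_energies: Dict[str, np.ndarray]


@dataclass(frozen=True)
class SignatureResult:
    network: str
    state: int
    pattern: str
    group_energies: Dict[str, np.ndarray]
    group_means: Dict[str, float]
    t_statistic: float
    p_value: float
    corrected_alpha: float
    significant: bool


def bonferroni_threshold(alpha: float, m: int) -> float:
    """The Bonferroni-corrected per-test level alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def two_sample_t(
    sample_a: Sequence[float], sample_b: Sequence[float], flavor: str = "pooled"
) -> Tuple[float, float]:
    """Two-sided two-sample t-test (pooled-variance Student or Welch)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateSampleError("each sample needs >= 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise DegenerateSampleError("zero within-group variance")
    if flavor not in ("pooled", "welch"):
        raise ValueError("flavor must be 'pooled' or 'welch'")
    res = sps.ttest_ind(a, b, equal_var=(flavor == "pooled"))
    return float(res.statistic), float(res.pvalue)


def subject_state_energy(
    subject_series: BinaryPatternSeries,
    state: int,
    fit_config: Optional[FitConfig] = None,
) -> float:
    """Energy of one state under the subject's own fitted MEM."""
    return subject_state_energies(subject_series, [state], fit_config)[0]


def subject_state_energies(
    subject_series: BinaryPatternSeries,
    states: Sequence[int],
    fit_config: Optional[FitConfig] = None,
    fit_result: Optional[FitResult] = None,
) -> np.ndarray:
    """Energies of several states under one subject's fitted MEM (one fit)."""
    if fit_result is None:
        fit_result = fit_mle(subject_series, fit_config)
    n = subject_series.n_regions
    return np.array(
        [energy(decode_state(s, n), fit_result.params) for s in states]
    )


def extract_signatures(
    candidates: Sequence[CandidateState], config: ComparisonConfig
) -> List[SignatureResult]:
    """Test every candidate state and flag Bonferroni-significant signatures.

    Results are sorted by ascending p-value; per-group mean energies are
    reported so the direction of the effect is readable.
    """
    corrected = bonferroni_threshold(config.alpha, config.m_comparisons)
    results: List[SignatureResult] = []
    for cand in candidates:
        if len(cand.group_energies) != 2:
            raise IncompleteInputError(
                f"state {cand.state} in {cand.network!r}: need exactly two "
                f"group samples, got {sorted(cand.group_energies)}"
            )
        (label_a, sample_a), (label_b, sample_b) = sorted(
            cand.group_energies.items()
        )
        for label, sample in ((label_a, sample_a), (label_b, sample_b)):
            if len(np.atleast_1d(sample)) < 2:
                raise IncompleteInputError(
                    f"state {cand.state} in {cand.network!r}: group "
                    f"{label!r} has fewer than 2 subject energies"
                )
        t, p = two_sample_t(sample_a, sample_b, config.test_flavor)
        results.append(
            SignatureResult(
                network=cand.network,
                state=cand.state,
                pattern="".join(
                    "+" if x > 0 else "-"
                    for x in decode_state(cand.state, cand.n_regions)
                ),
                group_energies={
                    label_a: np.asarray(sample_a, dtype=float),
                    label_b: np.asarray(sample_b, dtype=float),
                },
                group_means={
                    label_a: float(np.mean(sample_a)),
                    label_b: float(np.mean(sample_b)),
                },
                t_statistic=t,
                p_value=p,
                corrected_alpha=corrected,
                significant=bool(p < corrected),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.network, r.state))
    return results
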