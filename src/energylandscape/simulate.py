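"""Synthetic two-group studies drawn exactly from known Boltzmann laws.

Because 2^N is enumerable at the network sizes the analysis handles, binary
series are sampled i.i.d. by inverse-CDF lookup on the exact state
distribution — no MCMC, no mixing-time concerns.  The default study design
mirrors the two-group aging setting the pipeline targets: a 10-region
(attention-network-sized) ferromagnetic model with small bias jitter,
23 subjects in one group and 47 in the other, 500 volumes per subject.
"Effect" scenarios scale one group's couplings by a stated factor, which
lowers (strengthens coupling) or raises the energy of the all-active and
all-inactive states in that group.

A continuous surrogate maps ±1 to sigma + Gaussian noise so the
binarization stage can be exercised end to end; with sub-unit noise and a
balanced series, re-binarizing at the per-region mean recovers the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .binarize import ROITimeSeries, binarize
from .core import BinaryPatternSeries, MEMParams, all_patterns, boltzmann_distribution


@dataclass(frozen=True)
class SimulationSpec:
    """A two-group study design with one generating MEM per group."""

    n_regions: int
    params_by_group: Dict[str, MEMParams]
    subjects_per_group: Dict[str, int]
    t_max_per_subject: int
    seed: int
    continuous_surrogate: bool = False
    noise_scale: float = 0.1

    def __post_init__(self):
        if set(self.params_by_group) != set(self.subjects_per_group):
            raise ValueError("group labels of params and subject counts differ")
        for g, p in self.params_by_group.items():
            if p.n_regions != self.n_regions:
                raise ValueError(f"group {g!r} params have wrong dimension")
        if any(n < 1 for n in self.subjects_per_group.values()):
            raise ValueError("each group needs >= 1 subject")
        if self.t_max_per_subject < 1:
            raise ValueError("t_max_per_subject must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    group: str
    binary: BinaryPatternSeries
    continuous: Optional[ROITimeSeries] = None


def sample_patterns(
    params: MEMParams, t: int, seed=None, roi_names=None
) -> BinaryPatternSeries:
    """t i.i.d. draws from the exact 2^N-state Boltzmann distribution."""
    if t < 1:
        raise ValueError("t must be >= 1")
    rng = np.random.default_rng(seed)
    probs = boltzmann_distribution(params)
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    offsets = np.searchsorted(cdf, rng.random(t), side="right")
    data = all_patterns(params.n_regions)[offsets].T
    names = roi_names or tuple(f"roi{i + 1}" for i in range(params.n_regions))
    return BinaryPatternSeries(data=data, roi_names=names)


def make_continuous_surrogate(
    series: BinaryPatternSeries, noise_scale: float = 0.1, seed=None
) -> ROITimeSeries:
    """Map ±1 activity to sigma + Gaussian noise of the given scale.

    For noise_scale < 1 and a balanced series (every region's mean strictly
    inside (-1, 1)), thresholding the surrogate at the per-region mean
    recovers the input series exactly; a warning is raised when it does not
    (e.g. heavy noise or a nearly one-sided region).
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    data = series.data.astype(float)
    if noise_scale > 0:
        data = data + rng.normal(scale=noise_scale, size=data.shape)
    surrogate = ROITimeSeries(data=data, roi_names=series.roi_names)
    try:
        recovered = binarize(surrogate)
        ok = np.array_equal(recovered.data, series.data)
    except ValueError:
        ok = False
    if not ok:
        warnings.warn(
            "re-binarization of the continuous surrogate does not recover "
            "the source series (noise too large or series unbalanced)",
            stacklevel=2,
        )
    return surrogate


def make_two_group_dataset(spec: SimulationSpec) -> List[SyntheticSubject]:
    """Independent per-subject draws for every subject of both groups.

    Subject seeds are spawned deterministically from (spec.seed, group
    order, subject index), so the full dataset is byte-reproducible and
    distinct subjects get distinct streams.
    """
    root = np.random.SeedSequence(spec.seed)
    groups = sorted(spec.params_by_group)
    children = root.spawn(sum(spec.subjects_per_group.values()) * 2)
    subjects: List[SyntheticSubject] = []
    k = 0
    for group in groups:
        params = spec.params_by_group[group]
        for i in range(spec.subjects_per_group[group]):
            sid = f"{group}{i + 1:03d}"
            binary = sample_patterns(params, spec.t_max_per_subject, seed=children[k])
            continuous = None
            if spec.continuous_surrogate:
                continuous = make_continuous_surrogate(
                    binary, spec.noise_scale, seed=children[k + 1]
                )
                continuous = ROITimeSeries(
                    data=continuous.data,
                    roi_names=continuous.roi_names,
                    subject_id=sid,
                )
            k += 2
            subjects.append(
                SyntheticSubject(
                    subject_id=sid, group=group, binary=binary, continuous=continuous
                )
            )
    return subjects


# --------------------------------------------------------------------------
# default study design
# --------------------------------------------------------------------------

def ferromagnetic_params(
    n_regions: int,
    coupling: float = 0.12,
    h_jitter: float = 0.1,
    seed=0,
) -> MEMParams:
    """Uniform positive couplings with small random per-region biases.

    ``coupling`` is the J value shared by every region pair; 0.12 at N = 10
    keeps the model near (N-1)·J ≈ 1, cooperative but not frozen, so both
    all-active and all-inactive states are deep local minima without the
    sampler collapsing onto them.  ``h_jitter`` is the s.d. of the bias draw.
    """
    rng = np.random.default_rng(seed)
    J = np.full((n_regions, n_regions), float(coupling))
    np.fill_diagonal(J, 0.0)
    h = rng.normal(scale=h_jitter, size=n_regions) if h_jitter > 0 else np.zeros(n_regions)
    return MEMParams(h=h, J=J)


def scale_couplings(params: MEMParams, factor: float) -> MEMParams:
    """Same biases, couplings scaled by ``factor`` (the group-effect knob)."""
    return MEMParams(h=params.h.copy(), J=params.J * float(factor))


def default_spec(
    seed: int = 0,
    effect_scale: float = 1.0,
    n_regions: int = 10,
    subjects_young: int = 23,
    subjects_old: int = 47,
    t_max: int = 500,
    continuous_surrogate: bool = False,
) -> SimulationSpec:
    """The default two-group design: 23 "young" vs 47 "old" subjects.

    With ``effect_scale`` = 1 the groups share one generating model (a null
    study); smaller values weaken the old group's couplings, emulating the
    reduced within-network connectivity the analysis is built to detect.
    """
    young = ferromagnetic_params(n_regions, seed=seed)
    old = scale_couplings(young, effect_scale)
    return SimulationSpec(
        n_regions=n_regions,
        params_by_group={"young": young, "old": old},
        subjects_per_group={"young": subjects_young, "old": subjects_old},
        t_max_per_subject=t_max,
        seed=seed,
        continuous_surrogate=continuous_surrogate,
    )
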