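"""Continuous ROI time series: binarization, bilateral averaging, concatenation.

Each region's continuous signal is thresholded at its own time average to
give the ±1 activity sequence the pairwise MEM is fit to.  Networks with
more than 12 regions are first reduced by averaging homologous left/right
region pairs (averaging acts on the continuous signals, before
binarization).  Group-level series are built by concatenating the already
binarized per-subject series, so each subject keeps its own threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .core import BinaryPatternSeries


class DegenerateRegionError(ValueError):
    """A region has zero variance, so mean-thresholding is undefined."""


class AlignmentError(ValueError):
    """Series to be combined do not share the same ROI names/order."""


class BilateralMapError(ValueError):
    """A bilateral pair references a missing ROI or reuses one."""


@dataclass(frozen=True)
class ROITimeSeries:
    """Continuous ROI signals: N regions x t_max time points."""

    data: np.ndarray
    roi_names: Tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("data must be a non-empty N x t_max matrix")
        if not np.isfinite(data).all():
            raise ValueError("series contains missing or non-finite values")
        names = tuple(str(x) for x in self.roi_names)
        if len(names) != data.shape[0]:
            raise ValueError(f"{len(names)} roi_names for {data.shape[0]} regions")
        if len(set(names)) != len(names):
            raise ValueError("roi_names must be unique")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "roi_names", names)
        self.data.setflags(write=False)

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def t_max(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BilateralMap:
    """Homologous left/right region pairs to be averaged into one region.

    Each entry is (left_name, right_name, merged_name); a ROI may appear in
    at most one pair.
    """

    pairs: Tuple[Tuple[str, str, str], ...]

    def __post_init__(self):
        pairs = tuple((str(l), str(r), str(m)) for l, r, m in self.pairs)
        members = [name for l, r, _ in pairs for name in (l, r)]
        if len(set(members)) != len(members):
            raise BilateralMapError("a ROI appears in more than one bilateral pair")
        object.__setattr__(self, "pairs", pairs)


def binarize(series: ROITimeSeries) -> BinaryPatternSeries:
    """Threshold each region at its own time average.

    sigma_i(t) = +1 where the signal strictly exceeds region i's time mean,
    else -1 (values exactly at the mean map to -1).  A constant region makes
    the threshold degenerate and raises :class:`DegenerateRegionError`.
    """
    var = series.data.var(axis=1)
    if (var == 0).any():
        bad = series.roi_names[int(np.argmax(var == 0))]
        raise DegenerateRegionError(
            f"region {bad!r} is constant; mean-threshold binarization undefined"
        )
    means = series.data.mean(axis=1, keepdims=True)
    sigma = np.where(series.data > means, 1, -1).astype(np.int8)
    return BinaryPatternSeries(data=sigma, roi_names=series.roi_names)


def reduce_bilateral(series: ROITimeSeries, bmap: BilateralMap) -> ROITimeSeries:
    """Average homologous left/right pairs of continuous signals.

    Each pair is replaced by the pointwise mean of its two regions, placed at
    the position of the left member; unpaired regions pass through unchanged.
    Averaging happens on continuous signals, i.e. before binarization.
    """
    name_to_row = {name: i for i, name in enumerate(series.roi_names)}
    for left, right, _ in bmap.pairs:
        for name in (left, right):
            if name not in name_to_row:
                raise BilateralMapError(
                    f"bilateral pair member {name!r} not present in series "
                    f"{series.subject_id!r}"
                )
    right_of = {left: right for left, right, _ in bmap.pairs}
    merged_name = {left: merged for left, _, merged in bmap.pairs}
    drop = {right for _, right, _ in bmap.pairs}

    rows, names = [], []
    for name in series.roi_names:
        if name in drop:
            continue
        i = name_to_row[name]
        if name in right_of:
            j = name_to_row[right_of[name]]
            rows.append((series.data[i] + series.data[j]) / 2.0)
            names.append(merged_name[name])
        else:
            rows.append(series.data[i])
            names.append(name)
    return ROITimeSeries(
        data=np.vstack(rows), roi_names=tuple(names), subject_id=series.subject_id
    )


def concatenate_group(series_list: Sequence[BinaryPatternSeries]) -> BinaryPatternSeries:
    """Concatenate already-binarized subject series along time.

    All series must share ROI names and order; binarization is not
    re-applied, so each subject's own threshold is preserved.
    """
    if not series_list:
        raise ValueError("no series to concatenate")
    first = series_list[0]
    for s in series_list[1:]:
        if s.roi_names != first.roi_names:
            raise AlignmentError(
                f"ROI mismatch: {s.roi_names} vs {first.roi_names}"
            )
    return BinaryPatternSeries(
        data=np.hstack([s.data for s in series_list]), roi_names=first.roi_names
    )
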