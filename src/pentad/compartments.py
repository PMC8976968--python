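"""Compartment segmentation and enumeration of pile-up areas.

A compartment interval is a maximal run of consecutive bins whose signal
keeps a constant sign (positive = A, negative = B); missing bins terminate
runs. The five area types are: the on-diagonal squares of single intervals
(A_short / B_short), off-diagonal same-label rectangles (A_long / B_long)
and off-diagonal mixed-label rectangles (AB). In cis only the upper
triangle is enumerated (row interval precedes column interval).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .genome_io import BinnedTrack

__all__ = [
    "CompartmentInterval",
    "AreaDescriptor",
    "AREA_TYPES",
    "TRANS_AREA_TYPES",
    "DEFAULT_DISTANCE_BINS",
    "segment_signal",
    "enumerate_areas_cis",
    "enumerate_areas_trans",
    "anchor_distance",
    "assign_stratum",
]

AREA_TYPES = ("A_short", "B_short", "A_long", "B_long", "AB")
TRANS_AREA_TYPES = ("A_long", "B_long", "AB")

#: Default stratum boundaries for the by-distance mode, in bp.
DEFAULT_DISTANCE_BINS = (10_000_000, 25_000_000, 50_000_000, 100_000_000)


@dataclass(frozen=True)
class CompartmentInterval:
    chrom: str
    start: int  # bin index, inclusive
    end: int    # bin index, exclusive
    label: str  # "A" or "B"
    mean_signal: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError("interval end must exceed start")
        if self.label not in ("A", "B"):
            raise ValidationError(f"interval label must be A or B, got {self.label!r}")

    @property
    def n_bins(self) -> int:
        return self.end - self.start

    def midpoint(self) -> float:
        """Midpoint in bin units."""
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class AreaDescriptor:
    """One rectangular area of the O/E map: row interval x column interval."""

    row: CompartmentInterval
    col: CompartmentInterval
    kind: str                   # one of AREA_TYPES
    distance: float | None      # anchor distance in bp; None for trans
    context: str | tuple[str, str]

    @property
    def is_cis(self) -> bool:
        return isinstance(self.context, str)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row.n_bins, self.col.n_bins)


def segment_signal(track: BinnedTrack) -> list[CompartmentInterval]:
    """Run-length segmentation of the signal sign into A/B intervals."""
    values = np.asarray(track.values, dtype=np.float64)
    sign = np.zeros(len(values), dtype=np.int8)
    finite = np.isfinite(values)
    sign[finite & (values > 0)] = 1
    sign[finite & (values < 0)] = -1
    intervals: list[CompartmentInterval] = []
    start = None
    current = 0
    for i, s in enumerate(sign):
        if s != current:
            if current != 0:
                intervals.append(_make_interval(track, start, i, current, values))
            start = i if s != 0 else None
            current = s
    if current != 0:
        intervals.append(_make_interval(track, start, len(sign), current, values))
    return intervals


def _make_interval(track, start, end, sign, values) -> CompartmentInterval:
    return CompartmentInterval(
        chrom=track.chrom, start=start, end=end,
        label="A" if sign > 0 else "B",
        mean_signal=float(values[start:end].mean()),
    )


def anchor_distance(area: AreaDescriptor, binsize: int) -> float:
    """Midpoint-to-midpoint separation of the two intervals, in bp."""
    if not area.is_cis:
        raise ValidationError("anchor distance is undefined for trans areas")
    return abs(area.col.midpoint() - area.row.midpoint()) * binsize


def _midpoint_distance(row: CompartmentInterval, col: CompartmentInterval,
                       binsize: int) -> float:
    return abs(col.midpoint() - row.midpoint()) * binsize


def enumerate_areas_cis(
    intervals: Sequence[CompartmentInterval], binsize: int
) -> list[AreaDescriptor]:
    """All on-diagonal squares and ordered upper-triangle pairs.

    Emits n + n*(n-1)/2 descriptors for n intervals. Short-range
    (on-diagonal) areas carry anchor distance 0.
    """
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValidationError(f"cis enumeration got intervals from {sorted(chroms)}")
    areas: list[AreaDescriptor] = []
    for i, iv in enumerate(intervals):
        areas.append(AreaDescriptor(
            row=iv, col=iv, kind=f"{iv.label}_short", distance=0.0, context=iv.chrom,
        ))
        for jv in intervals[i + 1:]:
            kind = f"{iv.label}_long" if iv.label == jv.label else "AB"
            areas.append(AreaDescriptor(
                row=iv, col=jv, kind=kind,
                distance=_midpoint_distance(iv, jv, binsize),
                context=iv.chrom,
            ))
    return areas


def enumerate_areas_trans(
    intervals_row: Sequence[CompartmentInterval],
    intervals_col: Sequence[CompartmentInterval],
) -> list[AreaDescriptor]:
    """Full cross product of two chromosomes' intervals (n1*n2 areas)."""
    row_chroms = {iv.chrom for iv in intervals_row}
    col_chroms = {iv.chrom for iv in intervals_col}
    if row_chroms & col_chroms:
        raise ValidationError(
            f"trans enumeration requires distinct chromosomes, got {sorted(row_chroms & col_chroms)}"
        )
    areas = []
    for iv in intervals_row:
        for jv in intervals_col:
            kind = f"{iv.label}_long" if iv.label == jv.label else "AB"
            areas.append(AreaDescriptor(
                row=iv, col=jv, kind=kind, distance=None,
                context=(iv.chrom, jv.chrom),
            ))
    return areas


def assign_stratum(area: AreaDescriptor, boundaries: Sequence[float]) -> int | None:
    """Stratum index k with boundary_k <= anchor distance < boundary_{k+1}."""
    bounds = list(boundaries)
    if len(bounds) < 2 or any(b >= c for b, c in zip(bounds, bounds[1:])):
        raise ValidationError(
            f"distance boundaries must be strictly increasing with >=2 entries, got {bounds}"
        )
    if area.distance is None:
        raise ValidationError("cannot stratify a trans area (no anchor distance)")
    d = area.distance
    if d < bounds[0] or d >= bounds[-1]:
        return None
    return bisect_right(bounds, d) - 1
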