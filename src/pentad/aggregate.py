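"""Area extraction, filtering, bilinear rescaling and median aggregation.

The pentad is built by pooling, genome wide, the rescaled O/E submatrices
of every surviving area of a type and taking per-pixel medians. Missing
values propagate through the bilinear rescale (a target pixel is missing
whenever any source sample contributing to it is missing) and are ignored
by the median.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .compartments import (
    AREA_TYPES,
    DEFAULT_DISTANCE_BINS,
    TRANS_AREA_TYPES,
    AreaDescriptor,
    assign_stratum,
    enumerate_areas_cis,
    enumerate_areas_trans,
)
from .errors import ValidationError
from .genome_io import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AreaMatrix",
    "PentadSettings",
    "Pentad",
    "extract_area",
    "filter_areas",
    "rescale_area",
    "stack_median",
    "build_pentad",
    "panel_key",
]

#: Types whose areas sit off the diagonal and carry a positive anchor distance.
STRATIFIED_TYPES = ("A_long", "B_long", "AB")


@dataclass
class AreaMatrix:
    descriptor: AreaDescriptor
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.descriptor.shape:
            raise ValidationError(
                f"area values shape {self.values.shape} does not match descriptor "
                f"shape {self.descriptor.shape}"
            )


@dataclass(frozen=True)
class PentadSettings:
    """Filter and rescale settings shared by all pile-up modes."""

    rescale_size: int = 33
    min_dimension: int = 3
    max_zero_fraction: float = 0.5
    max_distance: float | None = None
    distance_bins: tuple[float, ...] = DEFAULT_DISTANCE_BINS

    def __post_init__(self):
        if self.rescale_size < 3 or self.rescale_size % 2 == 0:
            raise ValidationError(
                f"rescale size must be an odd integer >= 3, got {self.rescale_size}"
            )
        if not (0.0 <= self.max_zero_fraction <= 1.0):
            raise ValidationError(
                f"max zero fraction must lie in [0, 1], got {self.max_zero_fraction}"
            )

    def to_dict(self) -> dict:
        return {
            "rescale_size": self.rescale_size,
            "min_dimension": self.min_dimension,
            "max_zero_fraction": self.max_zero_fraction,
            "max_distance": self.max_distance,
            "distance_bins": list(self.distance_bins),
        }


def extract_area(oe: ContactMatrix, descriptor: AreaDescriptor) -> AreaMatrix:
    """Slice the O/E submatrix spanned by the descriptor's intervals."""
    n_rows, n_cols = oe.values.shape
    r, c = descriptor.row, descriptor.col
    if r.end > n_rows or c.end > n_cols or r.start < 0 or c.start < 0:
        raise ValidationError(
            f"area [{r.start},{r.end})x[{c.start},{c.end}) outside matrix of "
            f"shape {oe.values.shape}"
        )
    return AreaMatrix(
        descriptor=descriptor,
        values=oe.values[r.start:r.end, c.start:c.end].copy(),
    )


def filter_areas(
    areas: Sequence[AreaMatrix],
    min_dimension: int = 3,
    max_zero_fraction: float = 0.5,
    max_distance: float | None = None,
) -> tuple[list[AreaMatrix], dict[str, int]]:
    """Apply the three area filters; attribute each rejection to the
    first failing rule (dimensions, coverage, distance — in that order)."""
    if not (0.0 <= max_zero_fraction <= 1.0):
        raise ValidationError(
            f"max zero fraction must lie in [0, 1], got {max_zero_fraction}"
        )
    kept: list[AreaMatrix] = []
    rejected = {"dimension": 0, "coverage": 0, "distance": 0}
    for area in areas:
        rows, cols = area.values.shape
        if min(rows, cols) < min_dimension:
            rejected["dimension"] += 1
            continue
        empty = ~np.isfinite(area.values) | (area.values == 0)
        if empty.mean() > max_zero_fraction:
            rejected["coverage"] += 1
            continue
        if (
            max_distance is not None
            and area.descriptor.is_cis
            and area.descriptor.distance is not None
            and area.descriptor.distance > max_distance
        ):
            rejected["distance"] += 1
            continue
        kept.append(area)
    return kept, rejected


def rescale_area(area: AreaMatrix | np.ndarray, size: int) -> np.ndarray:
    """Bilinear rescale of a rectangular area into a size x size square.

    Sample centers of an n-long axis sit at (i + 0.5)/n on the unit
    interval; each target pixel center is mapped back onto that grid and
    interpolated from the (up to four) bracketing samples. Positions
    outside the outermost sample centers clamp to the edge sample. A
    target pixel is missing iff any source sample with positive weight is
    missing; a constant input stays constant.
    """
    if size < 3 or size % 2 == 0:
        raise ValidationError(f"rescale size must be an odd integer >= 3, got {size}")
    v = area.values if isinstance(area, AreaMatrix) else np.asarray(area, dtype=np.float64)
    if v.ndim != 2 or v.size == 0:
        raise ValidationError("rescale requires a non-empty 2-D array")

    def axis_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
        x = (np.arange(size) + 0.5) * n / size - 0.5
        x = np.clip(x, 0.0, n - 1.0)
        lo = np.minimum(np.floor(x).astype(np.intp), max(n - 2, 0))
        return lo, x - lo

    r0, wr = axis_coords(v.shape[0])
    c0, wc = axis_coords(v.shape[1])
    r1 = np.minimum(r0 + 1, v.shape[0] - 1)
    c1 = np.minimum(c0 + 1, v.shape[1] - 1)

    out = np.zeros((size, size))
    missing = np.zeros((size, size), dtype=bool)
    for ri, rw in ((r0, 1.0 - wr), (r1, wr)):
        for ci, cw in ((c0, 1.0 - wc), (c1, wc)):
            w = np.outer(rw, cw)
            sample = v[np.ix_(ri, ci)]
            active = w > 0
            out += np.where(active, w * sample, 0.0)
            missing |= active & ~np.isfinite(sample)
    out[missing] = np.nan
    return out


def stack_median(rescaled: Sequence[np.ndarray]) -> tuple[np.ndarray, int]:
    """Per-pixel median over non-missing values of same-size squares."""
    arrays = [np.asarray(a, dtype=np.float64) for a in rescaled]
    if not arrays:
        raise ValidationError("stack_median requires at least one array")
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValidationError(f"mixed array sizes in median stack: {sorted(shapes)}")
    stack = np.stack(arrays)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stack, axis=0)
    return med, len(arrays)


def panel_key(kind: str, stratum: int | None = None) -> str:
    return kind if stratum is None else f"{kind}@{stratum}"


@dataclass
class Pentad:
    """Median-aggregated average compartment panels plus provenance."""

    mode: str  # "cis", "trans" or "distance"
    size: int
    panels: dict[str, np.ndarray]
    counts: dict[str, int]
    settings: dict
    strata: list[float] | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        panels = {}
        for key, arr in self.panels.items():
            grid = [[None if not np.isfinite(x) else float(x) for x in row]
                    for row in np.asarray(arr)]
            panels[key] = {"values": grid, "count": int(self.counts[key])}
        return {
            "mode": self.mode,
            "size": self.size,
            "strata": self.strata,
            "settings": self.settings,
            "provenance": self.provenance,
            "panels": panels,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Pentad":
        panels, counts = {}, {}
        for key, entry in data["panels"].items():
            arr = np.array(
                [[np.nan if x is None else float(x) for x in row]
                 for row in entry["values"]],
                dtype=np.float64,
            )
            panels[key] = arr
            counts[key] = int(entry["count"])
        return cls(
            mode=data["mode"], size=int(data["size"]), panels=panels, counts=counts,
            settings=data.get("settings", {}), strata=data.get("strata"),
            provenance=data.get("provenance", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "Pentad":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _expected_keys(mode: str, strata: Sequence[float] | None) -> list[str]:
    if mode == "cis":
        return list(AREA_TYPES)
    if mode == "trans":
        return list(TRANS_AREA_TYPES)
    if mode == "distance":
        keys = ["A_short", "B_short"]
        n_strata = len(strata) - 1
        for kind in STRATIFIED_TYPES:
            keys.extend(panel_key(kind, k) for k in range(n_strata))
        return keys
    raise ValidationError(f"unknown pile-up mode {mode!r}")


def build_pentad(
    oe_maps: Mapping[str | tuple[str, str], ContactMatrix],
    intervals: Mapping[str, Sequence],
    mode: str,
    settings: PentadSettings | None = None,
    provenance: dict | None = None,
) -> Pentad:
    """Enumerate, extract, filter, rescale and median-stack areas genome wide.

    ``oe_maps`` is keyed by chromosome (cis/distance modes) or by
    chromosome pair (trans mode); ``intervals`` by chromosome.
    """
    settings = settings or PentadSettings()
    strata = list(settings.distance_bins) if mode == "distance" else None
    if mode == "distance" and (strata is None or len(strata) < 2):
        raise ValidationError("distance mode requires >=2 stratum boundaries")

    extracted: list[AreaMatrix] = []
    if mode in ("cis", "distance"):
        for chrom, oe in oe_maps.items():
            ivs = intervals.get(chrom)
            if not ivs:
                logger.warning("no compartment intervals for %s; skipped", chrom)
                continue
            for desc in enumerate_areas_cis(ivs, oe.binsize):
                extracted.append(extract_area(oe, desc))
    elif mode == "trans":
        for pair, oe in oe_maps.items():
            c1, c2 = pair
            ivs1, ivs2 = intervals.get(c1), intervals.get(c2)
            if not ivs1 or not ivs2:
                logger.warning("no intervals for pair (%s, %s); skipped", c1, c2)
                continue
            for desc in enumerate_areas_trans(ivs1, ivs2):
                extracted.append(extract_area(oe, desc))
    else:
        raise ValidationError(f"unknown pile-up mode {mode!r}")

    kept, rejected = filter_areas(
        extracted,
        min_dimension=settings.min_dimension,
        max_zero_fraction=settings.max_zero_fraction,
        max_distance=settings.max_distance,
    )

    buckets: dict[str, list[np.ndarray]] = {}
    for area in kept:
        kind = area.descriptor.kind
        if mode == "distance" and kind in STRATIFIED_TYPES:
            stratum = assign_stratum(area.descriptor, strata)
            if stratum is None:
                continue
            key = panel_key(kind, stratum)
        else:
            key = kind
        buckets.setdefault(key, []).append(rescale_area(area, settings.rescale_size))

    S = settings.rescale_size
    panels: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for key in _expected_keys(mode, strata):
        stack = buckets.get(key, [])
        if stack:
            panels[key], counts[key] = stack_median(stack)
        else:
            logger.warning("no areas survived filtering for panel %s", key)
            panels[key] = np.full((S, S), np.nan)
            counts[key] = 0

    prov = dict(provenance or {})
    prov.setdefault("rejected_areas", rejected)
    prov.setdefault("n_candidate_areas", len(extracted))
    return Pentad(
        mode=mode, size=S, panels=panels, counts=counts,
        settings=settings.to_dict(), strata=strata, provenance=prov,
    )
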