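"""Input readers: binned Hi-C contact matrices and compartment-signal tracks.

Coordinates are 0-based, half-open everywhere. A signal value of exactly 0
carries no compartment call and is stored as missing (NaN): the sign of the
value encodes membership (positive = A, negative = B) and sign is undefined
at zero.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._cooler import CoolerReader
from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeBins",
    "ContactMatrix",
    "BinnedTrack",
    "ValidationReport",
    "read_genome_bins",
    "read_contact_matrix",
    "read_compartment_signal",
    "validate_inputs",
]


@dataclass(frozen=True)
class GenomeBins:
    """A fixed-width bin grid over a set of chromosomes."""

    chromsizes: Mapping[str, int]
    binsize: int

    def __post_init__(self):
        if self.binsize <= 0:
            raise ValidationError(f"bin size must be positive, got {self.binsize}")
        for chrom, length in self.chromsizes.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chromsizes)

    def n_bins(self, chrom: str) -> int:
        if chrom not in self.chromsizes:
            raise ValidationError(f"chromosome {chrom!r} not in bin grid")
        return int(math.ceil(self.chromsizes[chrom] / self.binsize))


@dataclass
class ContactMatrix:
    """Dense contact matrix for one chromosome (cis) or pair (trans).

    Missing entries are NaN; all finite entries are >= 0.
    """

    row_chrom: str
    col_chrom: str
    values: np.ndarray
    binsize: int
    balanced: bool = False

    @property
    def is_cis(self) -> bool:
        return self.row_chrom == self.col_chrom

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("contact matrix must be two-dimensional")


@dataclass
class BinnedTrack:
    """Per-bin compartment signal for one chromosome (NaN = no call)."""

    chrom: str
    binsize: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class ValidationReport:
    shared_chromosomes: list[str]
    missing_fraction: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def read_genome_bins(path: str | os.PathLike, resolution: int | None = None) -> GenomeBins:
    """Bin grid of a cooler container."""
    reader = CoolerReader(path, resolution=resolution)
    return GenomeBins(chromsizes=reader.chromsizes, binsize=reader.binsize)


def read_contact_matrix(
    path: str | os.PathLike,
    region: str | tuple[str, str],
    use_balanced: bool | None = None,
    resolution: int | None = None,
) -> ContactMatrix:
    """Read one dense cis or trans matrix from a cooler container.

    ``use_balanced=None`` selects balanced values when weights are stored
    and falls back to raw counts (with a log message) otherwise; an
    explicit ``True`` without stored weights is an error.
    """
    reader = CoolerReader(path, resolution=resolution)
    if isinstance(region, str):
        c1 = c2 = region
    else:
        c1, c2 = region
    for c in {c1, c2}:
        reader.bin_range(c)  # raises ValidationError naming the chromosome
    if use_balanced is None:
        balanced = reader.has_weights
        if not balanced:
            logger.info("no balancing weights in %s; using raw counts", path)
    else:
        balanced = use_balanced
    values = reader.matrix(c1, c2, balanced=balanced)
    return ContactMatrix(
        row_chrom=c1, col_chrom=c2, values=values,
        binsize=reader.binsize, balanced=balanced,
    )


def read_compartment_signal(
    path: str | os.PathLike, bins: GenomeBins
) -> dict[str, BinnedTrack]:
    """Read a bedGraph compartment signal onto the matrix bin grid.

    Records spanning k bins expand to k per-bin values. Bins with no
    record, a value of exactly 0, or a non-finite value are missing.
    Chromosomes absent from ``bins`` are skipped with a warning.
    """
    if not os.path.exists(path):
        raise InputError(f"bedGraph file not found: {path}")
    binsize = bins.binsize
    values: dict[str, np.ndarray] = {}
    covered: dict[str, np.ndarray] = {}
    skipped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValidationError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}"
                )
            chrom, start_s, end_s, value_s = fields[:4]
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed record ({exc})") from None
            if chrom not in bins.chromsizes:
                skipped.add(chrom)
                continue
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: empty or inverted interval")
            chrom_len = bins.chromsizes[chrom]
            aligned_end = end % binsize == 0 or end == chrom_len
            if start % binsize != 0 or not aligned_end:
                raise ValidationError(
                    f"{path}:{lineno}: record [{start}, {end}) is not aligned to the "
                    f"{binsize} bp bin grid"
                )
            if end > chrom_len:
                raise ValidationError(
                    f"{path}:{lineno}: record end {end} exceeds {chrom} length {chrom_len}"
                )
            if chrom not in values:
                n = bins.n_bins(chrom)
                values[chrom] = np.full(n, np.nan)
                covered[chrom] = np.zeros(n, dtype=bool)
            b0 = start // binsize
            b1 = math.ceil(end / binsize)
            if covered[chrom][b0:b1].any():
                raise ValidationError(
                    f"{path}:{lineno}: record [{start}, {end}) overlaps an earlier "
                    f"record on {chrom}"
                )
            covered[chrom][b0:b1] = True
            if np.isfinite(value) and value != 0:
                values[chrom][b0:b1] = value
    for chrom in sorted(skipped):
        logger.warning("bedGraph chromosome %r absent from matrix bins; skipped", chrom)
    return {
        chrom: BinnedTrack(chrom=chrom, binsize=binsize, values=vals)
        for chrom, vals in values.items()
    }


def validate_inputs(
    matrix_bins: GenomeBins, tracks: Mapping[str, BinnedTrack]
) -> ValidationReport:
    """Check that matrix and signal share a bin grid and >=1 chromosome."""
    warnings: list[str] = []
    track_binsizes = {t.binsize for t in tracks.values()}
    if track_binsizes and track_binsizes != {matrix_bins.binsize}:
        raise ValidationError(
            f"bin-size mismatch: matrix at {matrix_bins.binsize} bp, "
            f"signal at {sorted(track_binsizes)[0]} bp"
        )
    shared = [c for c in matrix_bins.chroms if c in tracks]
    for chrom in tracks:
        if chrom not in matrix_bins.chromsizes:
            warnings.append(f"signal chromosome {chrom!r} absent from matrix; ignored")
    if not shared:
        raise ValidationError("matrix and compartment signal share no chromosomes")
    missing = {}
    for chrom in shared:
        track = tracks[chrom]
        n = matrix_bins.n_bins(chrom)
        if len(track.values) != n:
            raise ValidationError(
                f"track for {chrom} has {len(track.values)} bins, expected {n}"
            )
        missing[chrom] = float(np.mean(~np.isfinite(track.values)))
    for msg in warnings:
        logger.warning(msg)
    return ValidationReport(shared_chromosomes=shared, missing_fraction=missing,
                            warnings=warnings)
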