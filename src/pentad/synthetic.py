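"""Seeded synthetic Hi-C genomes with planted compartment structure.

The cis model is a distance-decay background modulated by a block
multiplier: entry (i, j) = depth * (|i-j| + 1)^(-alpha) * m(i, j) with
m = f when bins i and j share the planted label and 1/f otherwise; trans
entries drop the decay. Optional Poisson resampling mimics finite
sequencing depth, and a stated fraction of bins is blanked by assigning
them an undefined balancing weight. With f = 1 the genome is a
structureless null.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._cooler import write_cooler
from .compartments import CompartmentInterval
from .errors import ValidationError
from .genome_io import BinnedTrack, ContactMatrix, GenomeBins

__all__ = ["SyntheticSpec", "SyntheticGenome", "generate_genome", "write_fixture",
           "planted_oe_maps"]

_DEFAULT_CHROMS = {"chr1": 50_000_000, "chr2": 50_000_000}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic genome."""

    chromsizes: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_CHROMS))
    binsize: int = 100_000
    interval_bins: tuple[int, int] = (5, 15)  # sampled inclusive range, in bins
    layouts: Mapping[str, Sequence[int]] | None = None  # explicit run lengths, in bins
    f: float = 1.0
    alpha: float = 1.0
    depth: float = 1000.0
    depth_trans: float = 100.0
    noise: str = "none"  # "none" | "poisson"
    missing_fraction: float = 0.0
    trans: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.f < 1.0:
            raise ValidationError(f"planted contrast f must be >= 1, got {self.f}")
        if self.alpha <= 0:
            raise ValidationError(f"decay exponent must be positive, got {self.alpha}")
        if self.noise not in ("none", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValidationError(
                f"missing fraction must lie in [0, 1), got {self.missing_fraction}"
            )
        for chrom, length in self.chromsizes.items():
            if length % self.binsize != 0:
                raise ValidationError(
                    f"{chrom} length {length} is not a multiple of bin size {self.binsize}"
                )
        if self.layouts is not None:
            for chrom, runs in self.layouts.items():
                n = self.chromsizes[chrom] // self.binsize
                if sum(runs) != n:
                    raise ValidationError(
                        f"layout for {chrom} covers {sum(runs)} bins, expected {n}"
                    )


@dataclass
class SyntheticGenome:
    spec: SyntheticSpec
    bins: GenomeBins
    matrices: dict[tuple[str, str], np.ndarray]
    weights: dict[str, np.ndarray]
    tracks: dict[str, BinnedTrack]
    labels: dict[str, np.ndarray]  # per-bin +1 (A) / -1 (B)
    truth: dict


def _plant_labels(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    labels = {}
    lo, hi = spec.interval_bins
    for chrom, length in spec.chromsizes.items():
        n = length // spec.binsize
        if spec.layouts is not None and chrom in spec.layouts:
            runs = list(spec.layouts[chrom])
        else:
            runs = []
            total = 0
            while total < n:
                run = int(rng.integers(lo, hi + 1))
                runs.append(min(run, n - total))
                total += runs[-1]
        sign = np.empty(n, dtype=np.int8)
        pos = 0
        current = 1
        for run in runs:
            sign[pos:pos + run] = current
            pos += run
            current = -current
        labels[chrom] = sign
    return labels


def _cis_mean(spec: SyntheticSpec, sign: np.ndarray) -> np.ndarray:
    n = len(sign)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    decay = (d + 1.0) ** (-spec.alpha)
    m = np.where(np.equal.outer(sign, sign), spec.f, 1.0 / spec.f)
    return spec.depth * decay * m


def _trans_mean(spec: SyntheticSpec, sign1: np.ndarray, sign2: np.ndarray) -> np.ndarray:
    m = np.where(np.equal.outer(sign1, sign2), spec.f, 1.0 / spec.f)
    return spec.depth_trans * m


def _poissonize_cis(mean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = mean.shape[0]
    iu = np.triu_indices(n)
    out = np.zeros_like(mean)
    out[iu] = rng.poisson(mean[iu]).astype(np.float64)
    out.T[iu] = out[iu]
    return out


def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Deterministically generate matrices, tracks and ground truth."""
    rng = np.random.default_rng(spec.seed)
    labels = _plant_labels(spec, rng)
    bins = GenomeBins(chromsizes=dict(spec.chromsizes), binsize=spec.binsize)

    matrices: dict[tuple[str, str], np.ndarray] = {}
    for chrom, sign in labels.items():
        mean = _cis_mean(spec, sign)
        if spec.noise == "poisson":
            matrices[(chrom, chrom)] = _poissonize_cis(mean, rng)
        else:
            matrices[(chrom, chrom)] = mean
    if spec.trans:
        chroms = list(spec.chromsizes)
        for a in range(len(chroms)):
            for b in range(a + 1, len(chroms)):
                c1, c2 = chroms[a], chroms[b]
                mean = _trans_mean(spec, labels[c1], labels[c2])
                if spec.noise == "poisson":
                    matrices[(c1, c2)] = rng.poisson(mean).astype(np.float64)
                else:
                    matrices[(c1, c2)] = mean

    weights: dict[str, np.ndarray] = {}
    tracks: dict[str, BinnedTrack] = {}
    truth_intervals: dict[str, list[dict]] = {}
    for chrom, sign in labels.items():
        n = len(sign)
        w = np.ones(n)
        track_values = sign.astype(np.float64)
        n_missing = int(np.floor(spec.missing_fraction * n))
        if n_missing:
            blanked = rng.choice(n, size=n_missing, replace=False)
            w[blanked] = np.nan
            track_values[blanked] = 0.0  # zero = no call, masked on read
        weights[chrom] = w
        tracks[chrom] = BinnedTrack(chrom=chrom, binsize=spec.binsize, values=track_values)
        truth_intervals[chrom] = [
            {"start": iv.start, "end": iv.end, "label": iv.label}
            for iv in _intervals_from_track(tracks[chrom])
        ]

    truth = {
        "f": spec.f,
        "alpha": spec.alpha,
        "depth": spec.depth,
        "depth_trans": spec.depth_trans,
        "noise": spec.noise,
        "seed": spec.seed,
        "binsize": spec.binsize,
        "chromsizes": dict(spec.chromsizes),
        "intervals": truth_intervals,
    }
    return SyntheticGenome(
        spec=spec, bins=bins, matrices=matrices, weights=weights,
        tracks=tracks, labels=labels, truth=truth,
    )


def _intervals_from_track(track: BinnedTrack) -> list[CompartmentInterval]:
    from .compartments import segment_signal

    return segment_signal(track)


def planted_oe_maps(genome: SyntheticGenome) -> dict[str, ContactMatrix]:
    """Cis O/E maps normalized by the *known* generative expectation.

    Dividing each (possibly Poisson-noised) entry by depth * (d+1)^(-alpha)
    leaves the planted multiplier field: exactly f / (1/f) blocks in the
    noise-free case, an unbiased noisy estimate of them otherwise. Bins
    with undefined balancing weight are masked.
    """
    spec = genome.spec
    out = {}
    for (c1, c2), mat in genome.matrices.items():
        if c1 != c2:
            continue
        n = mat.shape[0]
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        expected = spec.depth * (d + 1.0) ** (-spec.alpha)
        oe = mat / expected
        w = genome.weights[c1]
        oe = oe * np.outer(w, w)  # NaN weights blank rows/columns
        out[c1] = ContactMatrix(row_chrom=c1, col_chrom=c1, values=oe,
                                binsize=spec.binsize, balanced=True)
    return out


def write_fixture(genome: SyntheticGenome, prefix: str | os.PathLike) -> dict[str, str]:
    """Write cooler container, bedGraph track and ground-truth JSON.

    Returns the paths written. Containers carry the genome's balancing
    weights (unit weights except for blanked bins), so balanced and raw
    reads agree wherever bins are defined.
    """
    prefix = os.fspath(prefix)
    cool_path = prefix + ".cool"
    bedgraph_path = prefix + ".bedgraph"
    truth_path = prefix + ".truth.json"

    write_cooler(
        cool_path, dict(genome.spec.chromsizes), genome.spec.binsize,
        genome.matrices, weights=genome.weights,
    )
    with open(bedgraph_path, "w") as fh:
        binsize = genome.spec.binsize
        for chrom, track in genome.tracks.items():
            values = track.values
            start = 0
            for i in range(1, len(values) + 1):
                if i == len(values) or values[i] != values[start]:
                    v = values[start]
                    if np.isfinite(v) and v != 0:
                        fh.write(f"{chrom}\t{start * binsize}\t{i * binsize}\t{v:g}\n")
                    start = i
    with open(truth_path, "w") as fh:
        json.dump(genome.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"cool": cool_path, "bedgraph": bedgraph_path, "truth": truth_path}
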