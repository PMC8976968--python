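"""Minimal reader/writer for the cooler HDF5 contact-matrix schema.

Implements the subset of the single-resolution schema (format-version 3)
needed here: ``chroms``, ``bins`` (with optional balancing ``weight``),
upper-triangle ``pixels`` and the ``chrom_offset`` / ``bin1_offset``
indexes, plus multi-resolution containers laid out under
``resolutions/<binsize>``. Counts are stored as float64 so synthetic
fixtures round-trip exactly.
"""

from __future__ import annotations

import math
import os
from typing import Mapping

import h5py
import numpy as np

from .errors import InputError, ValidationError

__all__ = ["CoolerReader", "write_cooler"]

_FORMAT = "HDF5::Cooler"
_MCOOL_FORMAT = "HDF5::MCOOL"


def _n_bins(length: int, binsize: int) -> int:
    return int(math.ceil(length / binsize))


def write_cooler(
    path: str | os.PathLike,
    chromsizes: Mapping[str, int],
    binsize: int,
    matrices: Mapping[tuple[str, str], np.ndarray],
    weights: Mapping[str, np.ndarray] | None = None,
    multires: bool = False,
) -> None:
    """Write dense per-region matrices as a cooler container.

    ``matrices`` maps ``(chrom, chrom)`` to a square cis matrix or
    ``(chrom1, chrom2)`` (in ``chromsizes`` order) to a rectangular trans
    matrix. Only finite nonzero entries of the upper triangle are stored.
    """
    names = list(chromsizes)
    order = {c: k for k, c in enumerate(names)}
    nbins_per = [_n_bins(chromsizes[c], binsize) for c in names]
    chrom_offset = np.concatenate([[0], np.cumsum(nbins_per)]).astype(np.int64)
    nbins = int(chrom_offset[-1])

    bin1_parts, bin2_parts, count_parts = [], [], []
    for (c1, c2), mat in matrices.items():
        if c1 not in order or c2 not in order:
            raise ValidationError(f"matrix region ({c1}, {c2}) not in chromsizes")
        mat = np.asarray(mat, dtype=np.float64)
        n1, n2 = nbins_per[order[c1]], nbins_per[order[c2]]
        if mat.shape != (n1, n2):
            raise ValidationError(
                f"matrix for ({c1}, {c2}) has shape {mat.shape}, expected {(n1, n2)}"
            )
        if c1 == c2:
            i, j = np.triu_indices(n1)
        else:
            if order[c1] >= order[c2]:
                raise ValidationError(
                    f"trans matrix key ({c1}, {c2}) must follow chromsizes order"
                )
            i, j = np.indices((n1, n2)).reshape(2, -1)
        vals = mat[i, j]
        keep = np.isfinite(vals) & (vals != 0)
        bin1_parts.append(chrom_offset[order[c1]] + i[keep])
        bin2_parts.append(chrom_offset[order[c2]] + j[keep])
        count_parts.append(vals[keep])

    if bin1_parts:
        bin1 = np.concatenate(bin1_parts)
        bin2 = np.concatenate(bin2_parts)
        count = np.concatenate(count_parts)
    else:
        bin1 = np.empty(0, dtype=np.int64)
        bin2 = np.empty(0, dtype=np.int64)
        count = np.empty(0, dtype=np.float64)
    sorter = np.lexsort((bin2, bin1))
    bin1, bin2, count = bin1[sorter], bin2[sorter], count[sorter]

    with h5py.File(path, "w") as f:
        if multires:
            f.attrs["format"] = _MCOOL_FORMAT
            f.attrs["format-version"] = np.int64(2)
            grp = f.create_group(f"resolutions/{binsize}")
        else:
            grp = f
        _write_body(
            grp, names, chromsizes, binsize, nbins_per, chrom_offset,
            bin1, bin2, count, weights,
        )


def _write_body(grp, names, chromsizes, binsize, nbins_per, chrom_offset,
                bin1, bin2, count, weights) -> None:
    nbins = int(chrom_offset[-1])
    grp.attrs["format"] = _FORMAT
    grp.attrs["format-version"] = np.int64(3)
    grp.attrs["bin-type"] = "fixed"
    grp.attrs["bin-size"] = np.int64(binsize)
    grp.attrs["storage-mode"] = "symmetric-upper"
    grp.attrs["nchroms"] = np.int64(len(names))
    grp.attrs["nbins"] = np.int64(nbins)
    grp.attrs["nnz"] = np.int64(len(count))
    grp.attrs["sum"] = float(count.sum())
    grp.attrs["generated-by"] = "pentad-0.1.0"

    chroms = grp.create_group("chroms")
    chroms.create_dataset("name", data=np.array(names, dtype=h5py.string_dtype("utf-8")))
    chroms.create_dataset("length", data=np.array([chromsizes[c] for c in names], dtype=np.int64))

    enum_dt = h5py.enum_dtype({name: k for k, name in enumerate(names)}, basetype=np.int32)
    chrom_ids = np.concatenate(
        [np.full(nb, k, dtype=np.int32) for k, nb in enumerate(nbins_per)]
    ) if nbins else np.empty(0, dtype=np.int32)
    starts = np.concatenate(
        [np.arange(nb, dtype=np.int64) * binsize for nb in nbins_per]
    ) if nbins else np.empty(0, dtype=np.int64)
    ends = np.concatenate(
        [np.minimum((np.arange(nb, dtype=np.int64) + 1) * binsize, chromsizes[c])
         for c, nb in zip(names, nbins_per)]
    ) if nbins else np.empty(0, dtype=np.int64)

    bins = grp.create_group("bins")
    bins.create_dataset("chrom", data=chrom_ids, dtype=enum_dt)
    bins.create_dataset("start", data=starts)
    bins.create_dataset("end", data=ends)
    if weights is not None:
        w = np.concatenate([np.asarray(weights[c], dtype=np.float64) for c in names])
        if len(w) != nbins:
            raise ValidationError("balancing weights do not cover every bin")
        bins.create_dataset("weight", data=w)

    pixels = grp.create_group("pixels")
    pixels.create_dataset("bin1_id", data=bin1.astype(np.int64))
    pixels.create_dataset("bin2_id", data=bin2.astype(np.int64))
    pixels.create_dataset("count", data=count.astype(np.float64))

    indexes = grp.create_group("indexes")
    indexes.create_dataset("chrom_offset", data=chrom_offset)
    indexes.create_dataset(
        "bin1_offset",
        data=np.searchsorted(bin1, np.arange(nbins + 1), side="left").astype(np.int64),
    )


class CoolerReader:
    """Read-only access to one resolution of a cooler container."""

    def __init__(self, path: str | os.PathLike, resolution: int | None = None):
        if not os.path.exists(path):
            raise InputError(f"cooler file not found: {path}")
        self.path = os.fspath(path)
        self._resolution = resolution
        with h5py.File(self.path, "r") as f:
            grp = self._group(f)
            names = [n.decode() if isinstance(n, bytes) else str(n)
                     for n in grp["chroms/name"][:]]
            lengths = grp["chroms/length"][:].astype(int)
            self.chromsizes = dict(zip(names, lengths))
            self.binsize = int(grp.attrs["bin-size"])
            self.has_weights = "weight" in grp["bins"]
            self._chrom_offset = grp["indexes/chrom_offset"][:].astype(np.int64)
        self._order = {c: k for k, c in enumerate(self.chromsizes)}

    def _group(self, f: h5py.File):
        if "resolutions" in f:
            available = sorted(int(r) for r in f["resolutions"])
            if self._resolution is None:
                raise ValidationError(
                    "multi-resolution container requires an explicit resolution; "
                    f"available: {available}"
                )
            if int(self._resolution) not in available:
                raise ValidationError(
                    f"resolution {self._resolution} not in container; available: {available}"
                )
            return f[f"resolutions/{int(self._resolution)}"]
        if self._resolution is not None and int(f.attrs["bin-size"]) != int(self._resolution):
            raise ValidationError(
                f"requested resolution {self._resolution} but container is binned at "
                f"{int(f.attrs['bin-size'])}"
            )
        return f

    def bin_range(self, chrom: str) -> tuple[int, int]:
        if chrom not in self._order:
            raise ValidationError(f"chromosome {chrom!r} not found in {self.path}")
        k = self._order[chrom]
        return int(self._chrom_offset[k]), int(self._chrom_offset[k + 1])

    def weights(self, chrom: str) -> np.ndarray | None:
        if not self.has_weights:
            return None
        lo, hi = self.bin_range(chrom)
        with h5py.File(self.path, "r") as f:
            return self._group(f)["bins/weight"][lo:hi].astype(np.float64)

    def matrix(self, chrom1: str, chrom2: str | None = None, balanced: bool = False) -> np.ndarray:
        """Dense matrix for a cis chromosome or a trans pair.

        The returned array is oriented rows=chrom1, cols=chrom2 regardless
        of storage order; cis matrices are symmetrized from the stored
        upper triangle.
        """
        chrom2 = chrom1 if chrom2 is None else chrom2
        if balanced and not self.has_weights:
            raise ValidationError(
                f"balanced matrix requested but {self.path} stores no balancing weights"
            )
        transpose = self._order.get(chrom1, -1) > self._order.get(chrom2, -1)
        ca, cb = (chrom2, chrom1) if transpose else (chrom1, chrom2)
        lo1, hi1 = self.bin_range(ca)
        lo2, hi2 = self.bin_range(cb)
        out = np.zeros((hi1 - lo1, hi2 - lo2), dtype=np.float64)
        with h5py.File(self.path, "r") as f:
            grp = self._group(f)
            b1off = grp["indexes/bin1_offset"][lo1:hi1 + 1]
            start, stop = int(b1off[0]), int(b1off[-1])
            if stop > start:
                bin1 = grp["pixels/bin1_id"][start:stop]
                bin2 = grp["pixels/bin2_id"][start:stop]
                cnt = grp["pixels/count"][start:stop].astype(np.float64)
                sel = (bin2 >= lo2) & (bin2 < hi2)
                out[bin1[sel] - lo1, bin2[sel] - lo2] = cnt[sel]
        if ca == cb:
            iu = np.triu_indices(out.shape[0], k=1)
            out[(iu[1], iu[0])] = out[iu]
        if balanced:
            w1 = self.weights(ca)
            w2 = self.weights(cb)
            out = out * np.outer(w1, w2)
        if transpose:
            out = out.T
        return out
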