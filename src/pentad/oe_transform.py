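"""Observed-over-expected normalization of contact matrices.

For cis matrices the expectation is the arithmetic mean of finite entries
at each genomic-distance offset of the same matrix; for trans matrices it
is the scalar mean over all finite entries. Means ignore missing entries,
and division by a zero or missing expected value yields missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .genome_io import ContactMatrix

__all__ = ["ExpectedProfile", "expected_cis", "oe_cis", "oe_trans"]


@dataclass
class ExpectedProfile:
    """Mean contact value per genomic-distance offset for one chromosome."""

    chrom: str
    values: np.ndarray  # length = matrix dimension; NaN where no finite entries

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


def expected_cis(matrix: ContactMatrix) -> ExpectedProfile:
    """Per-diagonal mean of finite entries over all (i, j) with |i-j| = d."""
    v = matrix.values
    if v.shape[0] != v.shape[1]:
        raise ValidationError(
            f"cis expected requires a square matrix, got shape {v.shape}"
        )
    n = v.shape[0]
    out = np.full(n, np.nan)
    for d in range(n):
        if d == 0:
            diag = np.diagonal(v)
        else:
            diag = np.concatenate([np.diagonal(v, offset=d), np.diagonal(v, offset=-d)])
        finite = diag[np.isfinite(diag)]
        if finite.size:
            out[d] = finite.mean()
    return ExpectedProfile(chrom=matrix.row_chrom, values=out)


def oe_cis(matrix: ContactMatrix, expected: ExpectedProfile) -> ContactMatrix:
    """Divide each entry by the expected value at its offset."""
    v = matrix.values
    if v.shape[0] != v.shape[1] or v.shape[0] != len(expected.values):
        raise ValidationError(
            f"matrix shape {v.shape} incompatible with expected profile of "
            f"length {len(expected.values)}"
        )
    n = v.shape[0]
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = expected.values[idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.where(np.isfinite(exp) & (exp != 0), v / exp, np.nan)
    return ContactMatrix(
        row_chrom=matrix.row_chrom, col_chrom=matrix.col_chrom,
        values=out, binsize=matrix.binsize, balanced=matrix.balanced,
    )


def oe_trans(matrix: ContactMatrix) -> ContactMatrix:
    """Divide a trans matrix by the scalar mean of its finite entries."""
    v = matrix.values
    finite = np.isfinite(v)
    if not finite.any():
        out = np.full_like(v, np.nan)
    else:
        mean = v[finite].mean()
        if mean == 0:
            out = np.full_like(v, np.nan)
        else:
            out = v / mean
    return ContactMatrix(
        row_chrom=matrix.row_chrom, col_chrom=matrix.col_chrom,
        values=out, binsize=matrix.binsize, balanced=matrix.balanced,
    )
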