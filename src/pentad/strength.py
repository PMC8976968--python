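"""Per-chromosome compartment strength and condition comparison.

Strength is the mean O/E of a within-compartment panel divided by the mean
O/E of the edge-cropped between-compartment (AB) panel; cropping removes
residual within-compartment signal at the AB panel edges. The combined
strength pools finite pixels from all four within panels over the same
cropped-AB denominator. Conditions are compared per area type with a
two-sided Wilcoxon signed-rank test on paired per-chromosome strengths.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import PentadSettings, build_pentad
from .errors import ValidationError
from .genome_io import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "STRENGTH_COLUMNS",
    "crop_center",
    "compartment_strength",
    "strength_genome",
    "compare_conditions",
    "write_strength_table",
    "read_strength_table",
    "write_comparison",
]

WITHIN_TYPES = ("A_short", "B_short", "A_long", "B_long")
STRENGTH_COLUMNS = WITHIN_TYPES + ("combined",)

#: Fraction of the panel size cropped from each side of the AB panel.
DEFAULT_CROP_FRACTION = 0.25


def crop_center(panel: np.ndarray, crop_fraction: float) -> np.ndarray:
    """Central (S-2k)x(S-2k) subarray with k = floor(crop_fraction * S)."""
    panel = np.asarray(panel)
    if panel.ndim != 2 or panel.shape[0] != panel.shape[1]:
        raise ValidationError(f"crop requires a square panel, got shape {panel.shape}")
    if not (0.0 <= crop_fraction < 0.5):
        raise ValidationError(
            f"crop fraction must lie in [0, 0.5), got {crop_fraction}"
        )
    s = panel.shape[0]
    k = math.floor(crop_fraction * s)
    if s - 2 * k < 1:
        raise ValidationError(f"cropping {k} pixels per side empties a {s}x{s} panel")
    return panel[k:s - k, k:s - k]


def _finite_mean(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    return float(finite.mean()) if finite.size else np.nan


def compartment_strength(
    panels: Mapping[str, np.ndarray],
    crop_fraction: float = DEFAULT_CROP_FRACTION,
) -> dict[str, float]:
    """One strength-table row from one chromosome's panels.

    All four within types share the cropped-AB denominator so they are
    comparable within a chromosome.
    """
    row: dict[str, float] = {c: np.nan for c in STRENGTH_COLUMNS}
    ab = panels.get("AB")
    if ab is None:
        return row
    denom = _finite_mean(crop_center(ab, crop_fraction))
    if not np.isfinite(denom) or denom == 0:
        if denom == 0:
            logger.warning("cropped AB panel mean is zero; strengths undefined")
        return row
    pooled: list[np.ndarray] = []
    for kind in WITHIN_TYPES:
        panel = panels.get(kind)
        if panel is None:
            continue
        finite = np.asarray(panel)[np.isfinite(panel)]
        if finite.size:
            row[kind] = float(finite.mean()) / denom
            pooled.append(finite)
    if pooled:
        row["combined"] = float(np.concatenate(pooled).mean()) / denom
    return row


def strength_genome(
    oe_maps: Mapping[str, ContactMatrix],
    intervals: Mapping[str, Sequence],
    settings: PentadSettings | None = None,
    crop_fraction: float = DEFAULT_CROP_FRACTION,
) -> pd.DataFrame:
    """StrengthTable: one row per chromosome, one column per area type.

    Per-chromosome pentads are built with the same filter settings as the
    genome-wide pile-up, but areas are never pooled across chromosomes.
    """
    settings = settings or PentadSettings()
    rows = {}
    for chrom, oe in oe_maps.items():
        ivs = intervals.get(chrom)
        if not ivs:
            logger.warning("no intervals for %s; strength row is missing", chrom)
            rows[chrom] = {c: np.nan for c in STRENGTH_COLUMNS}
            continue
        pentad = build_pentad({chrom: oe}, {chrom: ivs}, mode="cis", settings=settings)
        rows[chrom] = compartment_strength(pentad.panels, crop_fraction=crop_fraction)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(STRENGTH_COLUMNS))
    table.index.name = "chromosome"
    return table


def _significance_tier(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_conditions(
    table_1: pd.DataFrame, table_2: pd.DataFrame, min_pairs: int = 6
) -> pd.DataFrame:
    """Paired two-sided Wilcoxon signed-rank test per area type.

    Zero differences are dropped before ranking; for fewer than 26
    zero-free pairs the exact null distribution is used, otherwise the
    normal approximation with continuity correction. Below ``min_pairs``
    shared chromosomes a small-sample warning is logged.
    """
    shared = table_1.index.intersection(table_2.index)
    if len(shared) == 0:
        raise ValidationError("strength tables share no chromosomes")
    records = []
    for column in STRENGTH_COLUMNS:
        x = table_1.loc[shared, column].to_numpy(dtype=float)
        y = table_2.loc[shared, column].to_numpy(dtype=float)
        finite = np.isfinite(x) & np.isfinite(y)
        x, y = x[finite], y[finite]
        n = int(finite.sum())
        if n < min_pairs:
            logger.warning(
                "only %d finite pairs for %s; exact p-value reported but power is low",
                n, column,
            )
        diff = y - x
        nonzero = diff[diff != 0]
        if nonzero.size == 0:
            statistic, p_value = 0.0, 1.0
        else:
            method = "exact" if nonzero.size < 26 else "approx"
            result = stats.wilcoxon(
                nonzero, zero_method="wilcox", alternative="two-sided",
                correction=True, method=method,
            )
            statistic, p_value = float(result.statistic), float(result.pvalue)
        records.append({
            "type": column,
            "n": n,
            "statistic": statistic,
            "p_value": p_value,
            "significance": _significance_tier(p_value),
        })
    return pd.DataFrame.from_records(records)


def write_strength_table(table: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """TSV with '#'-prefixed provenance lines, header row, NA for missing."""
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, sep="\t", na_rep="NA")


def read_strength_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#", na_values="NA",
                        index_col="chromosome")
    return table


def write_comparison(report: pd.DataFrame, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        report.to_csv(fh, sep="\t", index=False)
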