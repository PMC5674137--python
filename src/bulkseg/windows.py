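"""Sliding-window BSA statistics: delta SNP-index, |delta SNP-index|, thresholds.

Per site, delta = index_a - index_b contrasts the two pools' allele frequencies;
a trait locus appears as a window where the averaged statistic departs from the
genome-wide background. When the parents are heterozygous and the reference genome
is a mosaic of haplotype states, the *sign* of delta flips at random reference
switch points, so windowed signed delta cancels toward zero while |delta| is
unaffected -- hence |delta| is the headline statistic for heterozygous crosses.

Windows are fixed-width (default 200 kb) advanced by a fixed step (default 20 kb),
1-based inclusive; windows overhanging the scaffold end are truncated, never
dropped. Thresholds are empirical quantiles of the non-missing window statistic
(default: the top 0.5 % of |delta| windows; for signed delta, a symmetric
0.25 % / 0.25 % pair is conventional). Flagging is strict (> upper, < lower).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, EmptyInputError
from .variants import PooledVariant

STATISTICS = ("delta", "abs_delta")

DEFAULT_WINDOW_SIZE = 200_000
DEFAULT_STEP = 20_000


def delta_index(variant: PooledVariant) -> float:
    """Signed SNP-index difference, pool A minus pool B (nan if either is missing).

    The sign's meaning depends on pool orientation (which pool is A) and, in
    heterozygous material, on the haplotype state of the reference -- record the
    orientation alongside any signed output.
    """
    return variant.index_a - variant.index_b


def abs_delta_index(variant: PooledVariant) -> float:
    """|delta_index|: sign-free pool contrast, robust to reference haplotype state."""
    return abs(delta_index(variant))


@dataclass
class Window:
    """One sliding window with averaged pool statistics.

    ``n_snps`` counts all variants whose position falls in [start, end]; each mean
    is taken over the variants with the relevant value(s) non-missing. ``mean_delta``
    and ``mean_abs_delta`` average over the same site set, so
    ``mean_abs_delta >= |mean_delta|`` always holds when defined.
    """

    scaffold: str
    start: int
    end: int
    n_snps: int = 0
    mean_index_a: float = math.nan
    mean_index_b: float = math.nan
    mean_delta: float = math.nan
    mean_abs_delta: float = math.nan

    def statistic(self, name: str) -> float:
        if name == "delta":
            return self.mean_delta
        if name == "abs_delta":
            return self.mean_abs_delta
        raise ValueError(f"unknown statistic {name!r}; expected one of {STATISTICS}")


@dataclass(frozen=True)
class ThresholdSet:
    """Quantile levels and the threshold values they realize on a window statistic."""

    statistic: str
    upper_quantile: float
    lower_quantile: float | None
    upper_value: float
    lower_value: float


def make_window_grid(
    scaffold: str,
    scaffold_length: int,
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
) -> list[Window]:
    """Empty window shells covering a scaffold.

    Windows start at 1, 1+step, 1+2*step, ... while the start lies on the
    scaffold; each ends at ``min(start + window_size - 1, scaffold_length)``
    (trailing windows are truncated).
    """
    if scaffold_length < 1:
        raise ValueError(f"scaffold_length must be >= 1, got {scaffold_length}")
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be positive")
    if step > window_size:
        raise ValueError(f"step ({step}) must not exceed window_size ({window_size})")
    windows = []
    start = 1
    while start <= scaffold_length:
        windows.append(
            Window(scaffold=scaffold, start=start, end=min(start + window_size - 1, scaffold_length))
        )
        start += step
    return windows


def window_statistics(
    variants: Sequence[PooledVariant],
    grid: Sequence[Window],
    min_snps: int = 1,
) -> list[Window]:
    """Fill a window grid with mean per-pool indices, mean delta and mean |delta|.

    ``variants`` must be position-sorted and on the grid's scaffold. A variant
    contributes to every window whose span contains it (window_size/step windows
    in the scaffold interior). Windows holding fewer than ``min_snps`` variants
    have all statistics set missing.
    """
    if not grid:
        return []
    scaffold = grid[0].scaffold
    for v in variants:
        if v.scaffold != scaffold:
            raise DataError(
                f"variant on {v.scaffold!r} passed to a {scaffold!r} window grid"
            )
    pos = np.fromiter((v.position for v in variants), dtype=np.int64, count=len(variants))
    if np.any(np.diff(pos) < 0):
        raise DataError("variants must be sorted by position")
    ia = np.fromiter((v.index_a for v in variants), dtype=float, count=len(variants))
    ib = np.fromiter((v.index_b for v in variants), dtype=float, count=len(variants))
    delta = ia - ib
    absd = np.abs(delta)

    starts = np.fromiter((w.start for w in grid), dtype=np.int64, count=len(grid))
    ends = np.fromiter((w.end for w in grid), dtype=np.int64, count=len(grid))
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")

    out: list[Window] = []
    for w, i, j in zip(grid, lo, hi):
        n = int(j - i)
        filled = Window(scaffold=w.scaffold, start=w.start, end=w.end, n_snps=n)
        if n >= max(min_snps, 1):
            filled.mean_index_a = _nanmean(ia[i:j])
            filled.mean_index_b = _nanmean(ib[i:j])
            filled.mean_delta = _nanmean(delta[i:j])
            filled.mean_abs_delta = _nanmean(absd[i:j])
        out.append(filled)
    return out


def _nanmean(values: np.ndarray) -> float:
    mask = ~np.isnan(values)
    n = int(mask.sum())
    if n == 0:
        return math.nan
    return float(values[mask].sum() / n)


def sliding_window_analysis(
    variants: Sequence[PooledVariant],
    scaffold_lengths: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
    min_snps: int = 1,
) -> list[Window]:
    """Window statistics for every scaffold in ``scaffold_lengths``.

    Variants must all lie on scaffolds present in the length table; scaffolds
    without variants still yield (empty) windows.
    """
    by_scaffold: dict[str, list[PooledVariant]] = {name: [] for name in scaffold_lengths}
    for v in variants:
        if v.scaffold not in by_scaffold:
            raise DataError(
                f"variant scaffold {v.scaffold!r} absent from the scaffold-length table"
            )
        by_scaffold[v.scaffold].append(v)
    windows: list[Window] = []
    for name, length in scaffold_lengths.items():
        grid = make_window_grid(name, length, window_size, step)
        windows.extend(window_statistics(by_scaffold[name], grid, min_snps=min_snps))
    return windows


def quantile_thresholds(
    windows: Iterable[Window],
    statistic: str = "abs_delta",
    upper_q: float = 0.005,
    lower_q: float | None = None,
) -> ThresholdSet:
    """Empirical quantile thresholds on a window-statistic distribution.

    ``upper_value`` is the (1 - upper_q) quantile of the non-missing window
    values (linear interpolation); ``lower_value`` the lower_q quantile when
    requested (used for the two-tailed signed-delta convention), nan otherwise.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    if not 0.0 < upper_q < 1.0:
        raise ValueError(f"upper_q must be in (0, 1), got {upper_q}")
    if lower_q is not None and not 0.0 < lower_q < 1.0:
        raise ValueError(f"lower_q must be in (0, 1), got {lower_q}")
    values = np.array([w.statistic(statistic) for w in windows], dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise EmptyInputError("no non-missing window statistics to set thresholds on")
    upper_value = float(np.quantile(values, 1.0 - upper_q))
    lower_value = float(np.quantile(values, lower_q)) if lower_q is not None else math.nan
    return ThresholdSet(
        statistic=statistic,
        upper_quantile=upper_q,
        lower_quantile=lower_q,
        upper_value=upper_value,
        lower_value=lower_value,
    )


def flag_windows(windows: Sequence[Window], thresholds: ThresholdSet) -> np.ndarray:
    """Boolean flags: strictly above the upper or below the lower threshold.

    Missing window statistics are never flagged. Strict inequalities mean a
    degenerate constant distribution flags nothing.
    """
    values = np.array([w.statistic(thresholds.statistic) for w in windows], dtype=float)
    flags = values > thresholds.upper_value
    if not math.isnan(thresholds.lower_value):
        flags |= values < thresholds.lower_value
    return flags


def windows_to_frame(windows: Sequence[Window]) -> pd.DataFrame:
    """Tabulate windows (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "scaffold": [w.scaffold for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "mean_index_a": [w.mean_index_a for w in windows],
            "mean_index_b": [w.mean_index_b for w in windows],
            "mean_delta": [w.mean_delta for w in windows],
            "mean_abs_delta": [w.mean_abs_delta for w in windows],
        }
    )


def write_windows_tsv(windows: Sequence[Window], path: str | Path) -> Path:
    """BED-like window table: 0-based half-open start, then end and the statistics."""
    path = Path(path)
    df = windows_to_frame(windows)
    df["start"] = df["start"] - 1
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
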