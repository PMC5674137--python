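"""Candidate-interval calling and genomic/genetic coordinate arithmetic.

Threshold-exceeding windows are merged (overlapping or abutting spans) into
scaffold-anchored candidate intervals whose boundaries land on the window grid.
Intervals supported by few, widely separated SNPs are filtered out.

Two length conventions coexist in published interval tables and are both
implemented: *inclusive* (end - start + 1; natural for window-grid regions whose
boundaries look like ...0001/...0000) and *difference* (end - start; natural for
marker-bounded spans quoted from marker coordinates). Every call and report states
the mode explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .variants import PooledVariant
from .windows import Window

LENGTH_UNITS = ("bp", "kb", "Mb")
LENGTH_MODES = ("inclusive", "difference")


@dataclass(frozen=True)
class GenomicInterval:
    """A scaffold-anchored 1-based inclusive span."""

    scaffold: str
    start: int
    end: int
    n_snps: int | None = None
    source: str = "window_call"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) must be >= start ({self.start})")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SparsityPolicy:
    """Drop rules for thinly supported intervals.

    An interval is removed when it contains fewer than ``min_snps`` SNPs or when
    the median gap between consecutive SNPs exceeds ``max_median_gap`` bp.
    """

    min_snps: int = 10
    max_median_gap: int = 20_000

    def __post_init__(self) -> None:
        if self.min_snps < 0:
            raise ConfigurationError(f"min_snps must be >= 0, got {self.min_snps}")
        if self.max_median_gap < 1:
            raise ConfigurationError(
                f"max_median_gap must be >= 1, got {self.max_median_gap}"
            )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of spans per scaffold; overlapping or abutting intervals merge."""
    ordered = sorted(intervals, key=lambda iv: (iv.scaffold, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].scaffold == iv.scaffold and iv.start <= merged[-1].end + 1:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end, n_snps=None)
        else:
            merged.append(replace(iv, n_snps=iv.n_snps))
    return merged


def call_intervals(
    windows: Sequence[Window],
    flags: Sequence[bool] | None = None,
    source: str = "window_call",
) -> list[GenomicInterval]:
    """Merged candidate intervals from threshold-exceeding windows.

    ``flags[i]`` marks whether ``windows[i]`` exceeds its threshold; if ``flags``
    is omitted every window is taken as flagged. Output intervals are disjoint,
    sorted, and independent of the input window order.
    """
    if flags is None:
        flagged = list(windows)
    else:
        if len(flags) != len(windows):
            raise DataError("flags and windows must have equal length")
        flagged = [w for w, f in zip(windows, flags) if f]
    spans = [
        GenomicInterval(scaffold=w.scaffold, start=w.start, end=w.end, source=source)
        for w in flagged
    ]
    return merge_intervals(spans)


@dataclass
class IntervalFilterResult:
    """Partition produced by :func:`filter_sparse` (reasons align with dropped)."""

    kept: list[GenomicInterval]
    dropped: list[GenomicInterval]
    reasons: list[str]


def filter_sparse(
    intervals: Sequence[GenomicInterval],
    variants: Sequence[PooledVariant],
    policy: SparsityPolicy | None = None,
) -> IntervalFilterResult:
    """Remove intervals supported by few or widely separated SNPs.

    Kept intervals carry an updated ``n_snps`` count. Idempotent.
    """
    policy = policy or SparsityPolicy()
    pos_lists: dict[str, list[int]] = {}
    for v in variants:
        pos_lists.setdefault(v.scaffold, []).append(v.position)
    positions = {k: np.sort(np.asarray(p, dtype=np.int64)) for k, p in pos_lists.items()}

    kept: list[GenomicInterval] = []
    dropped: list[GenomicInterval] = []
    reasons: list[str] = []
    for iv in intervals:
        pos = positions.get(iv.scaffold, np.empty(0, dtype=np.int64))
        inside = pos[np.searchsorted(pos, iv.start) : np.searchsorted(pos, iv.end, side="right")]
        n = int(inside.size)
        if n < policy.min_snps:
            dropped.append(iv)
            reasons.append("too_few_snps")
            continue
        if n >= 2 and float(np.median(np.diff(inside))) > policy.max_median_gap:
            dropped.append(iv)
            reasons.append("sparse_gaps")
            continue
        kept.append(replace(iv, n_snps=n))
    return IntervalFilterResult(kept=kept, dropped=dropped, reasons=reasons)


def interval_length(
    interval: GenomicInterval, unit: str = "bp", mode: str = "inclusive"
) -> float:
    """Interval length under an explicit convention.

    ``inclusive`` returns end - start + 1 (window-grid regions); ``difference``
    returns end - start (marker-bounded spans). Units: bp, kb (/1e3), Mb (/1e6).
    The value is unrounded; see :func:`format_length` for display rounding.
    """
    if mode not in LENGTH_MODES:
        raise ValueError(f"mode must be one of {LENGTH_MODES}, got {mode!r}")
    if unit not in LENGTH_UNITS:
        raise ValueError(f"unit must be one of {LENGTH_UNITS}, got {unit!r}")
    raw = interval.end - interval.start + (1 if mode == "inclusive" else 0)
    if unit == "bp":
        return float(raw)
    return raw / (1_000 if unit == "kb" else 1_000_000)


def total_length(
    intervals: Iterable[GenomicInterval], unit: str = "bp", mode: str = "inclusive"
) -> float:
    """Summed length of the merged interval set (overlaps never double-count)."""
    merged = merge_intervals(intervals)
    return float(sum(interval_length(iv, unit=unit, mode=mode) for iv in merged))


def format_length(interval_or_bp: GenomicInterval | float, unit: str = "kb") -> str:
    """Human-readable length: kb at one decimal, Mb at two, bp as an integer."""
    if isinstance(interval_or_bp, GenomicInterval):
        bp = float(interval_or_bp.length_bp)
    else:
        bp = float(interval_or_bp)
    if unit == "bp":
        return f"{bp:.0f} bp"
    if unit == "kb":
        return f"{bp / 1e3:.1f} kb"
    if unit == "Mb":
        return f"{bp / 1e6:.2f} Mb"
    raise ValueError(f"unit must be one of {LENGTH_UNITS}, got {unit!r}")


def map_distance(pos_a: float, pos_b: float) -> float:
    """Genetic distance between two linkage-map positions, in centimorgans."""
    return abs(pos_a - pos_b)


LINKAGE_MAP_COLUMNS = ("locus", "scaffold", "scaffold_position", "map_position_cM")


def read_linkage_map(path: str | Path) -> pd.DataFrame:
    """Read a linkage-map table (locus, scaffold, scaffold_position, map_position_cM)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LINKAGE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"linkage-map table {path} lacks columns: {missing}")
    return df


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Tabulate intervals in the 1-based inclusive convention with kb lengths."""
    return pd.DataFrame(
        {
            "scaffold": [iv.scaffold for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "length": [format_length(iv, "kb") for iv in intervals],
            "n_snps": [iv.n_snps if iv.n_snps is not None else "" for iv in intervals],
        }
    )


def write_intervals_tsv(intervals: Sequence[GenomicInterval], path: str | Path) -> Path:
    """Human-readable candidate-interval table with a total row (inclusive lengths)."""
    path = Path(path)
    df = intervals_to_frame(intervals)
    total = total_length(intervals, unit="bp", mode="inclusive")
    total_row = pd.DataFrame(
        [{"scaffold": "Total", "start": "", "end": "", "length": format_length(total, "Mb"), "n_snps": ""}]
    )
    pd.concat([df, total_row], ignore_index=True).to_csv(path, sep="\t", index=False)
    return path


def write_intervals_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> Path:
    """BED (0-based half-open) candidate intervals."""
    path = Path(path)
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.scaffold, x.start)):
            fh.write(f"{iv.scaffold}\t{iv.start - 1}\t{iv.end}\n")
    return path
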