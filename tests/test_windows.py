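"""Sliding-window grid construction, window statistics, quantile thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bulkseg import (
    DataError,
    PooledVariant,
    Window,
    abs_delta_index,
    apply_filters,
    delta_index,
    flag_windows,
    make_window_grid,
    quantile_thresholds,
    sliding_window_analysis,
    window_statistics,
)


def _variant(pos, a_alt, a_tot, b_alt, b_tot, scaffold="s1"):
    return PooledVariant(
        scaffold, pos, "A", "G", a_tot - a_alt, a_alt, b_tot - b_alt, b_alt
    )


# ---------------------------------------------------------------------------
# delta / |delta|
# ---------------------------------------------------------------------------


def test_delta_extreme_and_identity():
    assert delta_index(_variant(1, 20, 20, 0, 20)) == 1.0
    assert delta_index(_variant(1, 10, 20, 10, 20)) == 0.0


def test_delta_missing_propagates():
    v = _variant(1, 0, 0, 10, 20)
    assert math.isnan(delta_index(v))
    assert math.isnan(abs_delta_index(v))


def test_abs_delta_is_magnitude_of_delta(small_sim):
    for v in small_sim.variants[:500]:
        d = delta_index(v)
        a = abs_delta_index(v)
        if math.isnan(d):
            assert math.isnan(a)
        else:
            assert a == abs(d)


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


def test_grid_default_geometry():
    grid = make_window_grid("s1", 300_000)
    assert len(grid) == 15
    assert (grid[0].start, grid[0].end) == (1, 200_000)
    assert (grid[1].start, grid[1].end) == (20_001, 220_000)
    assert (grid[-1].start, grid[-1].end) == (280_001, 300_000)


def test_grid_scaffold_shorter_than_window_truncates():
    grid = make_window_grid("s1", 100_000)
    assert [(w.start, w.end) for w in grid] == [
        (1, 100_000),
        (20_001, 100_000),
        (40_001, 100_000),
        (60_001, 100_000),
        (80_001, 100_000),
    ]


def test_grid_degenerate_single_base():
    grid = make_window_grid("s1", 1, window_size=1, step=1)
    assert [(w.start, w.end) for w in grid] == [(1, 1)]


def test_grid_rejects_bad_sizes():
    with pytest.raises(ValueError):
        make_window_grid("s1", 1000, window_size=0)
    with pytest.raises(ValueError):
        make_window_grid("s1", 1000, window_size=100, step=200)
    with pytest.raises(ValueError):
        make_window_grid("s1", 0)


@given(
    length=st.integers(1, 2_000_000),
    window=st.integers(1, 500_000),
)
def test_grid_covers_scaffold_and_steps_uniformly(length, window):
    step = max(window // 10, 1)
    grid = make_window_grid("s1", length, window_size=window, step=step)
    assert grid[0].start == 1
    assert grid[-1].end == length
    for k, w in enumerate(grid):
        assert w.start == 1 + k * step
        assert w.end == min(w.start + window - 1, length)
        assert w.end - w.start + 1 <= window


# ---------------------------------------------------------------------------
# Window statistics
# ---------------------------------------------------------------------------


def test_window_mean_of_two_snps():
    variants = [_variant(10, 12, 20, 10, 20), _variant(50, 18, 20, 2, 20)]
    # |delta| = 0.1 and 0.8 -> window mean 0.45
    (w,) = window_statistics(variants, [Window("s1", 1, 200_000)])
    assert w.n_snps == 2
    assert w.mean_abs_delta == pytest.approx(0.45)
    assert w.mean_delta == pytest.approx(0.45)
    assert w.mean_index_a == pytest.approx((0.6 + 0.9) / 2)


def test_empty_window_all_statistics_missing():
    (w,) = window_statistics([], [Window("s1", 1, 200_000)])
    assert w.n_snps == 0
    for value in (w.mean_index_a, w.mean_index_b, w.mean_delta, w.mean_abs_delta):
        assert math.isnan(value)


def test_window_statistics_rejects_unsorted_input():
    variants = [_variant(50, 5, 10, 5, 10), _variant(10, 5, 10, 5, 10)]
    with pytest.raises(DataError):
        window_statistics(variants, [Window("s1", 1, 100)])


def test_window_statistics_rejects_wrong_scaffold():
    with pytest.raises(DataError):
        window_statistics([_variant(10, 5, 10, 5, 10, scaffold="s2")], [Window("s1", 1, 100)])


def _brute_force_window_means(variants, grid):
    """Independent oracle: rescan every variant for every window."""
    out = []
    for w in grid:
        absd = [
            abs_delta_index(v)
            for v in variants
            if v.scaffold == w.scaffold and w.start <= v.position <= w.end
        ]
        vals = [x for x in absd if not math.isnan(x)]
        out.append(sum(vals) / len(vals) if vals else math.nan)
    return out


def test_window_means_match_brute_force(small_sim):
    variants = [v for v in small_sim.variants if v.scaffold == "scaffold01"]
    grid = make_window_grid("scaffold01", 300_000, window_size=50_000, step=10_000)
    filled = window_statistics(variants, grid)
    oracle = _brute_force_window_means(variants, grid)
    for w, expected in zip(filled, oracle):
        if math.isnan(expected):
            assert math.isnan(w.mean_abs_delta)
        else:
            assert w.mean_abs_delta == pytest.approx(expected, abs=1e-12)


def test_variant_contributes_to_all_overlapping_windows():
    variants = [_variant(150_000, 5, 10, 5, 10)]
    grid = make_window_grid("s1", 400_000)
    filled = window_statistics(variants, grid)
    covering = [w for w in filled if w.start <= 150_000 <= w.end]
    assert len(covering) == 8  # interior coverage limited by scaffold start
    assert all(w.n_snps == 1 for w in covering)
    assert all(w.n_snps == 0 for w in filled if w not in covering)


def test_window_abs_mean_bounds_and_triangle_inequality(small_sim):
    kept = apply_filters(small_sim.variants).kept
    windows = sliding_window_analysis(kept, small_sim.scaffold_lengths)
    by_scaffold = {}
    for v in kept:
        by_scaffold.setdefault(v.scaffold, []).append(v)
    for w in windows:
        if math.isnan(w.mean_abs_delta):
            continue
        # the averaged-set triangle inequality: |mean(delta)| <= mean(|delta|)
        assert w.mean_abs_delta >= abs(w.mean_delta) - 1e-12
        inside = [
            abs_delta_index(v)
            for v in by_scaffold.get(w.scaffold, [])
            if w.start <= v.position <= w.end and not math.isnan(delta_index(v))
        ]
        assert min(inside) - 1e-12 <= w.mean_abs_delta <= max(inside) + 1e-12


def test_min_snps_marks_thin_windows_missing():
    variants = [_variant(10, 5, 10, 5, 10)]
    (w,) = window_statistics(variants, [Window("s1", 1, 100)], min_snps=2)
    assert w.n_snps == 1
    assert math.isnan(w.mean_abs_delta)


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------


def _windows_with_abs(values):
    return [
        Window("s1", 1 + i, 1 + i, n_snps=1, mean_abs_delta=v, mean_delta=v)
        for i, v in enumerate(values)
    ]


def test_top_half_percent_flags_exactly_five_of_1000():
    windows = _windows_with_abs([i / 1000 for i in range(1, 1001)])
    ts = quantile_thresholds(windows, "abs_delta", upper_q=0.005)
    flags = flag_windows(windows, ts)
    assert int(flags.sum()) == 5


def test_constant_statistic_flags_nothing_under_strict_rule():
    windows = _windows_with_abs([0.4] * 100)
    ts = quantile_thresholds(windows, "abs_delta", upper_q=0.01)
    assert ts.upper_value == pytest.approx(0.4)
    assert int(flag_windows(windows, ts).sum()) == 0


def test_symmetric_delta_gives_symmetric_thresholds():
    values = [x for i in range(1, 201) for x in (i / 200, -i / 200)]
    windows = [
        Window("s1", 1 + i, 1 + i, n_snps=1, mean_delta=v, mean_abs_delta=abs(v))
        for i, v in enumerate(values)
    ]
    ts = quantile_thresholds(windows, "delta", upper_q=0.025, lower_q=0.025)
    assert ts.lower_value == pytest.approx(-ts.upper_value)


@given(q=st.floats(0.001, 0.4), q2=st.floats(0.001, 0.4))
def test_threshold_monotone_in_quantile(q, q2):
    windows = _windows_with_abs([i / 500 for i in range(1, 501)])
    lo_q, hi_q = sorted((q, q2))
    t_small = quantile_thresholds(windows, "abs_delta", upper_q=lo_q)
    t_large = quantile_thresholds(windows, "abs_delta", upper_q=hi_q)
    assert t_large.upper_value <= t_small.upper_value


def test_missing_window_statistics_never_flagged_or_ranked():
    windows = _windows_with_abs([0.1, 0.2, 0.3]) + [Window("s1", 99, 99)]
    ts = quantile_thresholds(windows, "abs_delta", upper_q=0.34)
    flags = flag_windows(windows, ts)
    assert not flags[-1]
    assert ts.upper_value <= 0.3
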