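"""Grayscale mapping, normalization, and trajectory rasterization."""

import numpy as np
import pytest

from spiralad import (
    GrayImage,
    NormalizationStats,
    PenStream,
    RenderConfig,
    RenderError,
    fit_normalization,
    parameter_values,
    render_hybrid,
    render_raw,
    value_to_gray,
)

from conftest import random_stream


def stream_with(x, y, p=None, pen_down=None, alt=None):
    n = len(x)
    pen_down = np.ones(n, dtype=bool) if pen_down is None else np.asarray(pen_down, bool)
    p = np.where(pen_down, 10.0, 0.0) if p is None else np.asarray(p, float)
    return PenStream(
        subject_id="T", t=np.arange(n) / 125.0, x=x, y=y, p=p,
        az=np.zeros(n), alt=np.full(n, 45.0) if alt is None else alt, pen_down=pen_down,
    )


# ------------------------------------------------------------ value_to_gray

def test_gray_extremes_and_midpoint():
    stats = NormalizationStats("pressure", 0.0, 10.0)
    assert value_to_gray(10.0, stats) == 0      # population max -> black
    assert value_to_gray(0.0, stats) == 255     # population min -> white
    assert value_to_gray(5.0, stats) == 128     # round-half-up midpoint


def test_gray_clips_out_of_range():
    stats = NormalizationStats("pressure", 0.0, 10.0)
    assert value_to_gray(-5.0, stats) == 255
    assert value_to_gray(25.0, stats) == 0


def test_gray_degenerate_range_is_white():
    stats = NormalizationStats("pressure", 3.0, 3.0, degenerate=True)
    assert value_to_gray(3.0, stats) == 255


def test_gray_monotone_nonincreasing():
    stats = NormalizationStats("velocity", 0.0, 1.0)
    grays = [value_to_gray(v, stats) for v in np.linspace(-0.2, 1.2, 101)]
    assert all(a >= b for a, b in zip(grays, grays[1:]))


# -------------------------------------------------------- fit_normalization

def test_population_minmax_over_two_streams():
    s1 = stream_with([0, 1, 2], [0, 0, 0], p=[1, 3, 5])
    s2 = stream_with([0, 1, 2], [0, 0, 0], p=[3, 6, 9])
    stats = fit_normalization([s1, s2], "pressure")
    assert (stats.min_value, stats.max_value) == (1.0, 9.0)
    assert not stats.degenerate


def test_pressure_normalization_ignores_penups():
    s = stream_with(
        [0, 1, 2, 3], [0, 0, 0, 0], p=[5, 0, 0, 9],
        pen_down=[True, False, False, True],
    )
    stats = fit_normalization([s], "pressure")
    assert stats.min_value == 5.0  # in-air zeros do not contribute


def test_constant_parameter_flags_degenerate():
    s = stream_with([0, 1, 2], [0, 0, 0], p=[4, 4, 4])
    assert fit_normalization([s], "pressure").degenerate


def test_minmax_matches_bruteforce_scan(rng):
    streams = [random_stream(rng, n=20) for _ in range(10)]
    for parameter in ("pressure", "altitude", "velocity", "acceleration"):
        stats = fit_normalization(streams, parameter)
        pool = []
        for s in streams:
            vals = parameter_values(s, parameter)
            mask = s.pen_down if parameter == "pressure" else np.ones(len(s), bool)
            pool.extend(vals[mask].tolist())
        assert stats.min_value == min(pool) and stats.max_value == max(pool)


def test_empty_collection_rejected():
    with pytest.raises(ValueError):
        fit_normalization([], "pressure")


# ------------------------------------------------------------- rasterization

def _capsule_oracle(canvas_px, p0, p1, radius):
    """Brute force: every pixel whose center is within radius of the segment."""
    hits = set()
    (x0, y0), (x1, y1) = p0, p1
    dx, dy = x1 - x0, y1 - y0
    seg2 = dx * dx + dy * dy
    for r in range(canvas_px):
        for c in range(canvas_px):
            if seg2 == 0:
                d2 = (c - x0) ** 2 + (r - y0) ** 2
            else:
                t = min(max(((c - x0) * dx + (r - y0) * dy) / seg2, 0.0), 1.0)
                d2 = (c - (x0 + t * dx)) ** 2 + (r - (y0 + t * dy)) ** 2
            if d2 <= radius * radius:
                hits.add((r, c))
    return hits


def test_segment_pixels_match_bruteforce_capsule():
    s = stream_with([0.0, 10.0], [0.0, 4.0])
    config = RenderConfig(canvas_px=64, margin_frac=0.1, stroke_px=5)
    img = render_raw(s, config)
    ink = set(map(tuple, np.argwhere(img.pixels < 255)))
    # recompute the mapped endpoint coordinates independently
    span = 64 * 0.8
    scale = span / 10.0
    mid = 63 / 2.0
    px = [(-5.0) * scale + mid, 5.0 * scale + mid]
    py = [mid + 2.0 * scale, mid - 2.0 * scale]
    oracle = _capsule_oracle(64, (px[0], py[0]), (px[1], py[1]), 2.5)
    assert ink == oracle


def test_single_point_is_black_blob():
    s = stream_with([5.0], [5.0])
    img = render_raw(s, RenderConfig(canvas_px=64, stroke_px=3))
    ink = img.pixels < 255
    assert ink.any()
    assert np.all(img.pixels[ink] == 0)
    assert ink.sum() < 20  # a blob, not a trace


def test_raw_excludes_penups_and_is_deterministic():
    pen_down = [True, True, False, False, True, True]
    coords = list(range(6)), [0, 1, 5, 6, 2, 3]
    s = stream_with(coords[0], coords[1], pen_down=pen_down)
    config = RenderConfig(canvas_px=96)
    img1, img2 = render_raw(s, config), render_raw(s, config)
    np.testing.assert_array_equal(img1.pixels, img2.pixels)
    # the same trajectory drawn fully pen-down has strictly more ink,
    # and the pen-up version's ink is a subset of it
    full = render_raw(stream_with(coords[0], coords[1]), config)
    assert np.all(full.pixels[img1.pixels < 255] < 255)
    assert (full.pixels < 255).sum() > (img1.pixels < 255).sum()


def test_raw_without_pendown_rejected():
    s = stream_with([0, 1], [0, 0], p=[0, 0], pen_down=[False, False])
    with pytest.raises(RenderError):
        render_raw(s)


def test_raw_translation_invariance():
    coords = np.array([[0, 1, 3, 4.5], [0, 2, 1, 3]])
    a = stream_with(coords[0], coords[1])
    b = stream_with(coords[0] + 500.0, coords[1] - 200.0)
    np.testing.assert_array_equal(render_raw(a).pixels, render_raw(b).pixels)


# ------------------------------------------------------------ hybrid images

def test_constant_max_pressure_renders_black():
    s = stream_with([0, 1, 2, 3], [0, 1, 0, 1], p=[9, 9, 9, 9])
    stats = NormalizationStats("pressure", 0.0, 9.0)
    img = render_hybrid(s, "pressure", stats, RenderConfig(canvas_px=64))
    ink = img.pixels < 255
    assert ink.any() and np.all(img.pixels[ink] == 0)


def test_pressure_gap_velocity_bridge():
    """An in-air excursion breaks the pressure trace but not the velocity one."""
    n = 40
    pen_down = np.ones(n, dtype=bool)
    pen_down[18:22] = False
    # slow, varying pen-down motion; fast in-air excursion
    steps = np.where(pen_down, 1.0 + 0.5 * np.sin(np.arange(n)), 4.0)
    x = np.cumsum(steps)
    y = np.zeros(n)
    s = stream_with(x, y, p=np.where(pen_down, 400.0 + 5.0 * np.arange(n), 0.0), pen_down=pen_down)
    config = RenderConfig(canvas_px=128, stroke_px=3)
    p_img = render_hybrid(s, "pressure", fit_normalization([s], "pressure"), config)
    v_img = render_hybrid(s, "velocity", fit_normalization([s], "velocity"), config)
    mid_row = p_img.pixels.shape[0] // 2
    p_cols = np.flatnonzero(p_img.pixels[mid_row] < 255)
    v_cols = np.flatnonzero(v_img.pixels[mid_row] < 255)
    assert np.diff(p_cols).max() > 3, "pressure view must show a broken trajectory"
    # the in-air columns — the pressure view's gap — carry ink in velocity view
    gap_at = np.argmax(np.diff(p_cols))
    gap_lo, gap_hi = p_cols[gap_at], p_cols[gap_at + 1]
    bridge = [c for c in v_cols if gap_lo < c < gap_hi]
    assert bridge, "velocity view must bridge the pen-up gap"


def test_hybrid_ink_within_full_raw_ink(hc_stream):
    """Hybrid pixels lie inside the rendering of the full trajectory."""
    config = RenderConfig(canvas_px=128)
    stats = fit_normalization([hc_stream], "velocity", config=config)
    hybrid = render_hybrid(hc_stream, "velocity", stats, config)
    all_down = PenStream(
        subject_id=hc_stream.subject_id, t=hc_stream.t, x=hc_stream.x, y=hc_stream.y,
        p=np.ones(len(hc_stream)), az=hc_stream.az, alt=hc_stream.alt,
        pen_down=np.ones(len(hc_stream), dtype=bool),
    )
    full = render_raw(all_down, config)
    assert np.all(full.pixels[hybrid.pixels < 255] < 255)


def test_hybrid_monotone_in_parameter_values():
    """Raising every pressure value darkens (or keeps) every pixel."""
    x = np.arange(10.0)
    y = np.sin(x)
    stats = NormalizationStats("pressure", 0.0, 100.0)
    lo = stream_with(x, y, p=np.full(10, 30.0))
    hi = stream_with(x, y, p=np.full(10, 70.0))
    config = RenderConfig(canvas_px=96)
    img_lo = render_hybrid(lo, "pressure", stats, config)
    img_hi = render_hybrid(hi, "pressure", stats, config)
    assert np.all(img_hi.pixels <= img_lo.pixels)


def test_segment_gray_is_rounded_mean_of_endpoints():
    s = stream_with([0.0, 30.0], [0.0, 0.0], p=[0.0, 9.0])
    stats = NormalizationStats("pressure", 0.0, 9.0)
    img = render_hybrid(s, "pressure", stats, RenderConfig(canvas_px=64, stroke_px=3))
    mid_row = 63 // 2
    row = img.pixels[mid_row + 1]
    interior = row[(row < 255)]
    # endpoint grays 255 and 0 -> segment gray 128 dominates the middle
    assert 128 in interior


def test_gray_image_validates_range():
    with pytest.raises(ValueError):
        GrayImage(np.full((8, 8), 300), "raw")
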