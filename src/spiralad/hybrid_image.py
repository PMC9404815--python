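"""Rasterize spiral trajectories into raw and hybrid grayscale images.

A *raw* image shows only the shape of the pen-down trajectory, drawn in
black on white. A *hybrid* image embeds one dynamic parameter — pressure,
altitude, velocity, or acceleration — pointwise in the trajectory: each
rendered sample's parameter value is min-max normalized over the whole
study population and mapped to a gray level in [0, 255], low values white
and high values black. Views differ in which samples they render:

* pressure — pen-down samples only (in-air pressure is identically zero),
  so trajectories appear "broken" wherever the pen lifts;
* velocity, acceleration, altitude — pen-down and in-air samples, so the
  whole gesture is visible and in-air excursions are bridged.

Rendering uses connected thick segments: sample i is stamped as a disk at
its own gray level, and consecutive rendered samples are joined by a
capsule (all pixels within stroke/2 of the segment) at the rounded mean of
the endpoint grays. Overlaps keep the darkest value, so raising parameter
values can only darken the image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

from .pen_stream import PenStream, compute_acceleration, compute_velocity

logger = logging.getLogger("spiralad")

#: The four dynamic parameters that define hybrid views.
DYNAMIC_PARAMETERS = ("pressure", "altitude", "velocity", "acceleration")

#: All image views: the shape-only raw view plus the four hybrid views.
ALL_VIEWS = ("raw",) + DYNAMIC_PARAMETERS

BACKGROUND = 255


class RenderError(ValueError):
    """Unrenderable input (e.g. a stream with no pen-down samples)."""


def _check_parameter(parameter: str) -> None:
    if parameter not in DYNAMIC_PARAMETERS:
        raise ValueError(f"parameter must be one of {DYNAMIC_PARAMETERS}, got {parameter!r}")


@dataclass(frozen=True)
class NormalizationStats:
    """Population min-max range of one dynamic parameter.

    ``scope`` records whether the range was fitted on every subject
    ("all_subjects", the study protocol) or on training subjects only
    ("train_only", the leakage-free alternative). ``degenerate`` is set when
    max == min; all values then normalize to 0 (white).
    """

    parameter: str
    min_value: float
    max_value: float
    scope: str = "all_subjects"
    degenerate: bool = False

    def __post_init__(self) -> None:
        _check_parameter(self.parameter)
        if self.min_value > self.max_value:
            raise ValueError("min_value must be <= max_value")
        if self.scope not in ("all_subjects", "train_only"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class RenderConfig:
    """Geometry of the rasterization.

    canvas_px is the square canvas side; margin_frac the blank border
    fraction; stroke_px the stroke thickness. include_penups overrides, per
    parameter, whether in-air samples are rendered (defaults: pressure
    False, others True). connect_segments=False gives a dots-only rendering
    for ablation.
    """

    canvas_px: int = 512
    margin_frac: float = 0.05
    stroke_px: int = 3
    include_penups: Mapping[str, bool] = field(default_factory=dict)
    connect_segments: bool = True

    def __post_init__(self) -> None:
        if self.canvas_px < 64:
            raise ValueError("canvas_px must be >= 64")
        if not 0 <= self.margin_frac < 0.5:
            raise ValueError("margin_frac must be in [0, 0.5)")
        if self.stroke_px < 1:
            raise ValueError("stroke_px must be >= 1")

    def renders_penups(self, parameter: str) -> bool:
        _check_parameter(parameter)
        default = parameter != "pressure"
        return bool(self.include_penups.get(parameter, default))


@dataclass
class GrayImage:
    """An 8-bit grayscale rendering of one subject's spiral.

    view is "raw" or a dynamic parameter name; background is white (255).
    """

    pixels: np.ndarray
    view: str
    subject_id: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if self.pixels.dtype != np.uint8:
            if np.any((self.pixels < 0) | (self.pixels > 255)):
                raise ValueError("pixel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.view not in ALL_VIEWS:
            raise ValueError(f"view must be one of {ALL_VIEWS}, got {self.view!r}")

    def save(self, path) -> None:
        Image.fromarray(self.pixels, mode="L").save(path, format="PNG")

    @classmethod
    def load(cls, path, view: str = "raw", subject_id: str = "") -> "GrayImage":
        return cls(np.asarray(Image.open(path).convert("L")), view, subject_id)


# ---------------------------------------------------------------------------
# Parameter values and normalization
# ---------------------------------------------------------------------------

def parameter_values(stream: PenStream, parameter: str) -> np.ndarray:
    """Per-sample values of one dynamic parameter, aligned to the stream."""
    _check_parameter(parameter)
    if parameter == "pressure":
        return np.asarray(stream.p, dtype=float)
    if parameter == "altitude":
        return np.asarray(stream.alt, dtype=float)
    if parameter == "velocity":
        return compute_velocity(stream).values
    return compute_acceleration(stream).values


def _rendered_mask(stream: PenStream, parameter: str, config: RenderConfig) -> np.ndarray:
    if config.renders_penups(parameter):
        return np.ones(len(stream), dtype=bool)
    return np.asarray(stream.pen_down, dtype=bool)


def fit_normalization(
    streams: Iterable[PenStream],
    parameter: str,
    scope: str = "all_subjects",
    config: RenderConfig = RenderConfig(),
) -> NormalizationStats:
    """Min and max of one parameter over all rendered points of all streams.

    For pressure only pen-down points contribute (in-air pressure is
    identically 0 and never rendered). A constant parameter yields a
    degenerate range, flagged and logged; such values all normalize to 0.
    """
    _check_parameter(parameter)
    lo, hi = np.inf, -np.inf
    n_streams = 0
    for stream in streams:
        n_streams += 1
        mask = _rendered_mask(stream, parameter, config)
        values = parameter_values(stream, parameter)[mask]
        if values.size:
            lo = min(lo, float(values.min()))
            hi = max(hi, float(values.max()))
    if n_streams == 0 or not np.isfinite(lo):
        raise ValueError("fit_normalization needs at least one stream with rendered points")
    degenerate = lo == hi
    if degenerate:
        logger.warning("degenerate %s range (min == max == %g)", parameter, lo)
    return NormalizationStats(parameter, lo, hi, scope=scope, degenerate=degenerate)


def value_to_gray(value: float, stats: NormalizationStats) -> int:
    """Map a parameter value to a gray level: min -> 255 (white), max -> 0.

    Normalized values are clipped to [0, 1]; rounding is half-up, so the
    midpoint maps to 128. Degenerate stats map everything to white.
    """
    if stats.degenerate:
        return 255
    vhat = (value - stats.min_value) / (stats.max_value - stats.min_value)
    if vhat < 0 or vhat > 1:
        logger.debug("clipping out-of-range %s value %g", stats.parameter, value)
        vhat = min(max(vhat, 0.0), 1.0)
    return int(np.floor(255.0 * (1.0 - vhat) + 0.5))


def _values_to_gray(values: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    if stats.degenerate:
        return np.full(values.shape, 255, dtype=int)
    vhat = np.clip((values - stats.min_value) / (stats.max_value - stats.min_value), 0.0, 1.0)
    return np.floor(255.0 * (1.0 - vhat) + 0.5).astype(int)


# ---------------------------------------------------------------------------
# Geometry and rasterization
# ---------------------------------------------------------------------------

def _canvas_coords(stream: PenStream, config: RenderConfig) -> tuple[np.ndarray, np.ndarray]:
    """Affine map of tablet coordinates to pixel coordinates (col, row).

    The bounding box of the *full* trajectory (pen-down and in-air) is
    mapped into the canvas with margin, aspect ratio preserved and
    centered, so all views of one subject share the same geometry. The
    y-axis is flipped: tablet "up" is image "up".
    """
    x = np.asarray(stream.x, dtype=float)
    y = np.asarray(stream.y, dtype=float)
    span = config.canvas_px * (1.0 - 2.0 * config.margin_frac)
    w = float(x.max() - x.min()) if x.size else 0.0
    h = float(y.max() - y.min()) if y.size else 0.0
    scale = span / max(w, h) if max(w, h) > 0 else 0.0
    cx = (x.min() + x.max()) / 2.0 if x.size else 0.0
    cy = (y.min() + y.max()) / 2.0 if y.size else 0.0
    mid = (config.canvas_px - 1) / 2.0
    px = (x - cx) * scale + mid
    py = mid - (y - cy) * scale
    return px, py


def _stamp_capsule(
    canvas: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    gray: int,
    radius: float,
) -> None:
    """Darken all pixels within `radius` of segment p0-p1 to at most `gray`.

    A pixel belongs to the capsule when the distance from its center to the
    segment is <= radius. Accumulation takes the minimum (darkest wins).
    """
    n = canvas.shape[0]
    x0, y0 = p0
    x1, y1 = p1
    lo_c = max(int(np.floor(min(x0, x1) - radius)), 0)
    hi_c = min(int(np.ceil(max(x0, x1) + radius)), n - 1)
    lo_r = max(int(np.floor(min(y0, y1) - radius)), 0)
    hi_r = min(int(np.ceil(max(y0, y1) + radius)), n - 1)
    if lo_c > hi_c or lo_r > hi_r:
        return
    cols = np.arange(lo_c, hi_c + 1, dtype=float)
    rows = np.arange(lo_r, hi_r + 1, dtype=float)[:, None]
    dx, dy = x1 - x0, y1 - y0
    seg2 = dx * dx + dy * dy
    if seg2 == 0.0:
        d2 = (cols - x0) ** 2 + (rows - y0) ** 2
    else:
        tt = np.clip(((cols - x0) * dx + (rows - y0) * dy) / seg2, 0.0, 1.0)
        d2 = (cols - (x0 + tt * dx)) ** 2 + (rows - (y0 + tt * dy)) ** 2
    patch = canvas[lo_r : hi_r + 1, lo_c : hi_c + 1]
    np.minimum(patch, np.where(d2 <= radius * radius, gray, 255), out=patch)


def _render(
    stream: PenStream,
    mask: np.ndarray,
    grays: np.ndarray,
    config: RenderConfig,
    view: str,
    degenerate: bool = False,
) -> GrayImage:
    if not mask.any():
        raise RenderError(f"stream {stream.subject_id!r} has no renderable samples for view {view!r}")
    px, py = _canvas_coords(stream, config)
    canvas = np.full((config.canvas_px, config.canvas_px), BACKGROUND, dtype=np.int16)
    radius = config.stroke_px / 2.0
    idx = np.flatnonzero(mask)
    for i in idx:
        _stamp_capsule(canvas, (px[i], py[i]), (px[i], py[i]), int(grays[i]), radius)
    if config.connect_segments:
        consecutive = idx[:-1][(np.diff(idx) == 1)]
        for i in consecutive:
            seg_gray = int(np.floor((grays[i] + grays[i + 1]) / 2.0 + 0.5))
            _stamp_capsule(canvas, (px[i], py[i]), (px[i + 1], py[i + 1]), seg_gray, radius)
    return GrayImage(canvas.astype(np.uint8), view, stream.subject_id, degenerate=degenerate)


def render_raw(stream: PenStream, config: RenderConfig = RenderConfig()) -> GrayImage:
    """Shape-only rendering: pen-down trajectory in black on white.

    In-air samples are not drawn and consecutive pen-down samples separated
    by an in-air excursion are not bridged.
    """
    mask = np.asarray(stream.pen_down, dtype=bool)
    if not mask.any():
        raise RenderError(f"stream {stream.subject_id!r} has no pen-down samples")
    grays = np.zeros(len(stream), dtype=int)
    return _render(stream, mask, grays, config, "raw")


def render_hybrid(
    stream: PenStream,
    parameter: str,
    stats: NormalizationStats,
    config: RenderConfig = RenderConfig(),
) -> GrayImage:
    """Dynamics-encoded rendering of one parameter.

    Each rendered sample is stamped at its own gray level; segments joining
    consecutive rendered samples take the rounded mean of the endpoint
    grays. The pressure view renders pen-down samples only; velocity,
    acceleration and altitude views render the full gesture.
    """
    _check_parameter(parameter)
    if stats.parameter != parameter:
        raise ValueError(f"stats fitted for {stats.parameter!r}, not {parameter!r}")
    mask = _rendered_mask(stream, parameter, config)
    values = parameter_values(stream, parameter)
    grays = _values_to_gray(values, stats)
    return _render(stream, mask, grays, config, parameter, degenerate=stats.degenerate)


def render_views(
    streams: Sequence[PenStream],
    views: Sequence[str] = ALL_VIEWS,
    scope: str = "all_subjects",
    config: RenderConfig = RenderConfig(),
) -> tuple[dict[str, dict[str, GrayImage]], dict[str, NormalizationStats]]:
    """Render a cohort in several views with population normalization.

    Returns ({view: {subject_id: image}}, {parameter: stats}).
    """
    stats: dict[str, NormalizationStats] = {}
    images: dict[str, dict[str, GrayImage]] = {}
    for view in views:
        if view == "raw":
            images[view] = {s.subject_id: render_raw(s, config) for s in streams}
        else:
            stats[view] = fit_normalization(streams, view, scope=scope, config=config)
            images[view] = {
                s.subject_id: render_hybrid(s, view, stats[view], config) for s in streams
            }
    return images, stats
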