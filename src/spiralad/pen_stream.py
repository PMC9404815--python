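"""Online pen recordings: data model, file I/O, and kinematics.

A digitizing tablet samples the pen trajectory (nominally at 125 Hz) and
captures five temporal functions per sample — position x(t), y(t), pressure
p(t), and the two barrel-orientation angles azimuth Az(t) and altitude
Alt(t) — together with a pen-down flag. The tablet also records the in-air
("pen-up") trajectory close to the surface; in-air samples carry zero
pressure.

Pen velocity and acceleration are first-order finite differences of the
position channels::

    vx(t) = (x(t+1) - x(t)) / dt       v(t) = sqrt(vx^2 + vy^2)
    ax(t) = (vx(t+1) - vx(t)) / dt     a(t) = sqrt(ax^2 + ay^2)

The derivative value is assigned to the earlier sample and the tail is
padded by replication so every kinematic series has the same length as its
source stream, which keeps pointwise rendering trivial.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger("spiralad")

#: Nominal digitizer sampling rate in Hz.
DEFAULT_SAMPLE_RATE_HZ = 125.0

#: Columns of the canonical pen-stream TSV dialect, in order.
CANONICAL_COLUMNS = ("t_ms", "x", "y", "p", "az", "alt", "pen_down")

VALID_LABELS = ("AD", "HC", "unknown")


class PenStreamError(ValueError):
    """Invalid pen-stream content (parse failure or invariant violation)."""


class DegenerateInputError(PenStreamError):
    """Stream too short for the requested operation."""


class PenSample(NamedTuple):
    """One digitizer sample.

    t is seconds from stream start; x/y are tablet units; p is device
    pressure units (0 whenever the pen is in the air); az in [0, 360)
    degrees; alt in [0, 90] degrees.
    """

    t: float
    x: float
    y: float
    p: float
    az: float
    alt: float
    pen_down: bool


@dataclass
class PenStream:
    """One subject's time-ordered pen recording.

    Channels are stored as parallel numpy arrays; ``stream[i]`` yields a
    :class:`PenSample` view of sample ``i``.
    """

    subject_id: str = ""
    label: str = "unknown"
    t: np.ndarray = field(default_factory=lambda: np.empty(0))
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))
    p: np.ndarray = field(default_factory=lambda: np.empty(0))
    az: np.ndarray = field(default_factory=lambda: np.empty(0))
    alt: np.ndarray = field(default_factory=lambda: np.empty(0))
    pen_down: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        arrays = {
            "t": np.asarray(self.t, dtype=float),
            "x": np.asarray(self.x, dtype=float),
            "y": np.asarray(self.y, dtype=float),
            "p": np.asarray(self.p, dtype=float),
            "az": np.asarray(self.az, dtype=float),
            "alt": np.asarray(self.alt, dtype=float),
        }
        pen_down = np.asarray(self.pen_down, dtype=bool)
        n = arrays["t"].shape[0]
        for name, arr in arrays.items():
            if arr.ndim != 1 or arr.shape[0] != n:
                raise PenStreamError(f"channel {name!r} must be 1-D of length {n}")
        if pen_down.shape != (n,):
            raise PenStreamError("pen_down length mismatch")
        for name, arr in arrays.items():
            setattr(self, name, arr)
        self.pen_down = pen_down
        self.validate()

    def validate(self) -> None:
        """Check the stream invariants, raising :class:`PenStreamError`."""
        if self.label not in VALID_LABELS:
            raise PenStreamError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        n = len(self)
        if n > 1 and not np.all(np.diff(self.t) > 0):
            i = int(np.argmin(np.diff(self.t) > 0))
            raise PenStreamError(f"time not strictly increasing at sample {i + 1}")
        if np.any(self.p < 0):
            raise PenStreamError("pressure must be >= 0")
        up = ~self.pen_down
        if np.any(self.p[up] != 0):
            i = int(np.flatnonzero(up & (self.p != 0))[0])
            raise PenStreamError(f"pen-up sample {i} has nonzero pressure")
        if np.any((self.alt < 0) | (self.alt > 90)):
            raise PenStreamError("altitude outside [0, 90] degrees")
        if np.any((self.az < 0) | (self.az >= 360)):
            raise PenStreamError("azimuth outside [0, 360) degrees")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    def __getitem__(self, i: int) -> PenSample:
        return PenSample(
            float(self.t[i]), float(self.x[i]), float(self.y[i]), float(self.p[i]),
            float(self.az[i]), float(self.alt[i]), bool(self.pen_down[i]),
        )

    def __iter__(self) -> Iterator[PenSample]:
        return (self[i] for i in range(len(self)))


@dataclass(frozen=True)
class KinematicSeries:
    """Per-sample kinematic magnitudes aligned to the source stream.

    ``parameter`` is "velocity" or "acceleration"; values are nonnegative
    magnitudes in tablet units per second (or per second squared), one per
    source sample (tail replicated).
    """

    parameter: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.parameter not in ("velocity", "acceleration"):
            raise ValueError(f"unknown kinematic parameter {self.parameter!r}")
        if np.any(self.values < 0):
            raise ValueError("kinematic magnitudes must be >= 0")


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def _component_velocities(stream: PenStream) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed per-interval component velocities (length n-1) and interval dt."""
    dt = np.diff(stream.t)
    return np.diff(stream.x) / dt, np.diff(stream.y) / dt, dt


def compute_velocity(stream: PenStream) -> KinematicSeries:
    """Pointwise pen speed |v| from first differences of position.

    The value for interval [t_i, t_{i+1}] is assigned to sample i; the last
    sample replicates its predecessor so the series matches the stream
    length. Pen-up (in-air) samples are included: the tablet records the
    in-air trajectory and its speed is part of the gesture.
    """
    if len(stream) < 2:
        raise DegenerateInputError("velocity needs at least 2 samples")
    vx, vy, _ = _component_velocities(stream)
    v = np.hypot(vx, vy)
    return KinematicSeries("velocity", np.append(v, v[-1]))


def compute_acceleration(stream: PenStream) -> KinematicSeries:
    """Pointwise pen acceleration |a| from differences of component velocity.

    Uses the signed component velocities (vx, vy), not the speed magnitude,
    so uniform circular-ish motion keeps its centripetal component. Values
    are assigned to the earlier sample; the final two samples replicate the
    last computed value.
    """
    if len(stream) < 3:
        raise DegenerateInputError("acceleration needs at least 3 samples")
    vx, vy, dt = _component_velocities(stream)
    ax = np.diff(vx) / dt[:-1]
    ay = np.diff(vy) / dt[:-1]
    a = np.hypot(ax, ay)
    return KinematicSeries("acceleration", np.concatenate([a, [a[-1], a[-1]]]))


def split_pen_states(stream: PenStream) -> list[tuple[bool, int, int]]:
    """Maximal runs of constant pen state as (state, start, end) inclusive.

    The runs partition the index range exactly; an empty stream yields [].
    """
    n = len(stream)
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(stream.pen_down.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [n - 1]])
    return [(bool(stream.pen_down[s]), int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Canonical TSV I/O
# ---------------------------------------------------------------------------

def write_pen_stream(stream: PenStream, path) -> None:
    """Write the canonical pen-stream TSV.

    UTF-8, tab-separated, header ``t_ms x y p az alt pen_down``, preceded by
    ``# subject_id=...`` and ``# label=...`` comment lines. Floats are
    written at full repr precision; times sampled on a regular millisecond
    grid round-trip exactly.
    """
    buf = io.StringIO()
    buf.write(f"# subject_id={stream.subject_id}\n")
    buf.write(f"# label={stream.label}\n")
    buf.write(f"# sample_rate_hz={stream.sample_rate_hz:g}\n")
    buf.write("\t".join(CANONICAL_COLUMNS) + "\n")
    t_ms = stream.t * 1000.0
    for i in range(len(stream)):
        row = (
            repr(float(t_ms[i])), repr(float(stream.x[i])), repr(float(stream.y[i])),
            repr(float(stream.p[i])), repr(float(stream.az[i])), repr(float(stream.alt[i])),
            "1" if stream.pen_down[i] else "0",
        )
        buf.write("\t".join(row) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


@dataclass(frozen=True)
class StreamDialect:
    """Columnar dialect of a pen-stream text file.

    ``columns`` names the file's columns in order using the canonical names
    (``t_ms``/``t_s`` optional — when absent, time is synthesized as
    index / sample_rate). ``sep=None`` means any whitespace.
    """

    columns: Sequence[str] = CANONICAL_COLUMNS
    sep: str | None = "\t"
    has_header: bool = True
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ


CANONICAL_DIALECT = StreamDialect()


def read_pen_stream(path, dialect: StreamDialect = CANONICAL_DIALECT) -> PenStream:
    """Parse a pen-stream text file into a validated :class:`PenStream`.

    Raises :class:`PenStreamError` naming the offending line on malformed
    rows, and on invariant violations (non-monotone time, pressure on
    pen-up rows, angle ranges).
    """
    meta = {"subject_id": "", "label": "unknown", "sample_rate_hz": dialect.sample_rate_hz}
    rows: list[list[str]] = []
    header_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key = key.strip()
                    if key in ("subject_id", "label"):
                        meta[key] = value.strip()
                    elif key == "sample_rate_hz":
                        meta[key] = float(value)
                continue
            if dialect.has_header and not header_seen:
                header_seen = True
                continue
            parts = line.split(dialect.sep) if dialect.sep else line.split()
            if len(parts) != len(dialect.columns):
                raise PenStreamError(
                    f"{path}: line {lineno}: expected {len(dialect.columns)} fields, got {len(parts)}"
                )
            rows.append([lineno, *parts])

    cols: dict[str, list[float]] = {name: [] for name in dialect.columns}
    for row in rows:
        lineno, *parts = row
        for name, token in zip(dialect.columns, parts):
            try:
                cols[name].append(float(token))
            except ValueError as exc:
                raise PenStreamError(
                    f"{path}: line {lineno}: bad value {token!r} for column {name!r}"
                ) from exc

    n = len(rows)
    rate = float(meta["sample_rate_hz"])
    if "t_ms" in cols:
        t = np.asarray(cols["t_ms"]) / 1000.0
    elif "t_s" in cols:
        t = np.asarray(cols["t_s"])
    else:
        t = np.arange(n) / rate
    try:
        return PenStream(
            subject_id=str(meta["subject_id"]),
            label=str(meta["label"]),
            t=t,
            x=cols.get("x", np.zeros(n)),
            y=cols.get("y", np.zeros(n)),
            p=cols.get("p", np.zeros(n)),
            az=cols.get("az", np.zeros(n)),
            alt=cols.get("alt", np.zeros(n)),
            pen_down=np.asarray(cols.get("pen_down", np.ones(n)), dtype=float) != 0,
            sample_rate_hz=rate,
        )
    except PenStreamError as exc:
        raise PenStreamError(f"{path}: {exc}") from exc
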