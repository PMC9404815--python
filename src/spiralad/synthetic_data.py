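"""Synthetic spiral cohorts: labeled HC-like and AD-like pen recordings.

The clinical recordings behind this methodology are private, so the
package ships a generator of plausible Archimedes-spiral executions with a
controllable class contrast. A subject traverses r(θ) = spiral_gap·θ with:

* Ornstein–Uhlenbeck-perturbed angular speed (smooth speed fluctuation);
* sinusoidal radial tremor in the 4–7 Hz action-tremor band;
* AR(1) pressure noise around a linearly drifting mean, clipped at 0;
* AR(1) altitude around a mean pen inclination, clipped to [0, 90];
* slowly drifting azimuth;
* a Poisson number of in-air excursions during which the pen lifts
  (pen_down False, zero pressure) and moves faster.

The AD profile is the HC profile shifted by an effect size ε ∈ [0, 1]
toward "full-AD" deltas: more radial tremor, more speed jitter, lower mean
pressure with higher pressure variability, more in-air excursions, and
more variable pen altitude — echoing the qualitative contrasts the hybrid
images are designed to expose (light/broken pressure traces, fast in-air
bridges). At ε = 0 the class distributions are identical; magnitudes are
configuration, not claims about real disease. Streams are sampled at
125 Hz like the acquisition hardware.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .pen_stream import DEFAULT_SAMPLE_RATE_HZ, PenStream

logger = logging.getLogger("spiralad")


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters for one subject class.

    Units: tablet units for lengths and pressure (device units), seconds
    for time, degrees for angles, rad/s for angular speed.
    """

    n_turns: float = 4.0
    spiral_gap: float = 30.0          # radial growth per radian
    base_speed: float = 2.0           # mean angular speed, rad/s
    speed_jitter_sd: float = 0.08     # relative sd of angular speed
    tremor_amp: float = 0.5           # radial tremor amplitude
    tremor_hz: tuple[float, float] = (4.0, 7.0)  # per-subject U[lo, hi]
    pressure_mean: float = 600.0
    pressure_sd: float = 25.0
    pressure_drift: float = -2.0      # device units per second
    penup_rate: float = 0.5           # expected in-air excursions per spiral
    penup_dur_s: float = 0.25         # mean excursion duration
    penup_speed_factor: float = 2.5   # angular-speed inflation while in air
    alt_mean: float = 55.0
    alt_sd: float = 2.0
    az_drift: float = 2.0             # degrees per second

    def __post_init__(self) -> None:
        for name in ("speed_jitter_sd", "pressure_sd", "alt_sd", "tremor_amp", "penup_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.alt_mean <= 90.0:
            raise ValueError("alt_mean must lie in [0, 90] degrees")

    def profile_hash(self) -> str:
        payload = repr(dataclasses.astuple(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


#: Deltas added to the HC profile at full effect size (ε = 1).
FULL_AD_DELTAS: dict[str, float] = {
    "tremor_amp": 2.5,
    "speed_jitter_sd": 0.22,
    "pressure_mean": -250.0,
    "pressure_sd": 45.0,
    "penup_rate": 3.5,
    "alt_sd": 6.0,
}


def ad_profile(hc: SubjectProfile, effect_size: float, deltas: dict[str, float] | None = None) -> SubjectProfile:
    """HC profile shifted by ε times the full-AD deltas."""
    if not 0.0 <= effect_size <= 1.0:
        raise ValueError("effect_size must lie in [0, 1]")
    deltas = FULL_AD_DELTAS if deltas is None else deltas
    changes = {k: getattr(hc, k) + effect_size * dv for k, dv in deltas.items()}
    return dataclasses.replace(hc, **changes)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and effect size.

    Defaults mirror the study cohort: 45 HC and 30 AD, one spiral each,
    sampled at 125 Hz.
    """

    n_hc: int = 45
    n_ad: int = 30
    effect_size: float = 1.0
    seed: int = 0
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    hc_profile: SubjectProfile = SubjectProfile()
    ad_deltas: tuple[tuple[str, float], ...] = tuple(sorted(FULL_AD_DELTAS.items()))

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")

    @property
    def ad_profile(self) -> SubjectProfile:
        return ad_profile(self.hc_profile, self.effect_size, dict(self.ad_deltas))


# ---------------------------------------------------------------------------
# Single-subject simulation
# ---------------------------------------------------------------------------

_MAX_DURATION_S = 90.0
_OU_REVERSION = 2.0  # 1/s, mean-reversion rate of angular speed
_AR1_RHO = 0.95      # pressure / altitude noise memory per sample


def _simulate_angle(
    profile: SubjectProfile,
    rng: np.random.Generator,
    dt: float,
    speed_boost: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate OU angular speed until the spiral's total angle is covered.

    Returns (theta, omega) arrays. ``speed_boost`` is an optional per-sample
    multiplicative factor (used for in-air speed inflation on a second pass).
    """
    total_angle = 2.0 * np.pi * profile.n_turns
    mu = profile.base_speed
    sd = profile.speed_jitter_sd * mu
    n_max = int(_MAX_DURATION_S / dt)
    omega = np.empty(n_max)
    theta = np.empty(n_max)
    w = mu
    th = 0.0
    k = np.exp(-_OU_REVERSION * dt)
    noise_sd = sd * np.sqrt(max(1.0 - k * k, 0.0))
    eps = rng.normal(0.0, 1.0, size=n_max) if sd > 0 else np.zeros(n_max)
    n = n_max
    for i in range(n_max):
        boost = speed_boost[i] if speed_boost is not None and i < len(speed_boost) else 1.0
        omega[i] = max(w * boost, 0.05 * mu)
        theta[i] = th
        th += omega[i] * dt
        w = mu + k * (w - mu) + noise_sd * eps[i]
        if th >= total_angle:
            n = i + 1
            break
    return theta[:n], omega[:n]


def _ar1(n: int, sd: float, rng: np.random.Generator, rho: float = _AR1_RHO) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho * rho), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov[i]
    return out


def generate_subject(
    profile: SubjectProfile,
    seed: int,
    subject_id: str = "",
    label: str = "unknown",
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> PenStream:
    """Simulate one spiral execution as a validated PenStream.

    Deterministic in (profile, seed). In-air excursions are placed in time
    (Poisson count, exponential durations), lift the pen, zero the
    pressure, and inflate the angular speed.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz

    # First pass without excursions fixes the approximate duration, so
    # excursions can be placed uniformly in time.
    theta0, _ = _simulate_angle(profile, np.random.default_rng(seed + 1), dt)
    t_end = len(theta0) * dt

    n_penups = rng.poisson(profile.penup_rate)
    n_max = int(_MAX_DURATION_S / dt)
    pen_down = np.ones(n_max, dtype=bool)
    if n_penups > 0:
        starts = np.sort(rng.uniform(0.05 * t_end, 0.75 * t_end, size=n_penups))
        durs = np.clip(rng.exponential(profile.penup_dur_s, size=n_penups), 0.04, 1.5)
        # shift overlapping excursions later so each stays a distinct run
        prev_end = -np.inf
        for s, d in zip(starts, durs):
            s = max(s, prev_end + 2.0 * dt)
            i0, i1 = int(s / dt), int((s + d) / dt) + 1
            pen_down[i0:i1] = False
            prev_end = s + d
    boost = np.where(pen_down, 1.0, profile.penup_speed_factor)

    theta, _ = _simulate_angle(profile, np.random.default_rng(seed + 1), dt, speed_boost=boost)
    n = len(theta)
    t = np.arange(n) * dt
    pen_down = pen_down[:n]

    f_tremor = rng.uniform(*profile.tremor_hz)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    r = profile.spiral_gap * theta + profile.tremor_amp * np.sin(
        2.0 * np.pi * f_tremor * t + phase
    )
    x = r * np.cos(theta)
    y = r * np.sin(theta)

    p = profile.pressure_mean + profile.pressure_drift * t + _ar1(n, profile.pressure_sd, rng)
    p = np.clip(p, 0.0, None)
    p[~pen_down] = 0.0

    alt = np.clip(profile.alt_mean + _ar1(n, profile.alt_sd, rng), 0.0, 90.0)
    az = (rng.uniform(0.0, 360.0) + profile.az_drift * t) % 360.0

    return PenStream(
        subject_id=subject_id,
        label=label,
        t=t, x=x, y=y, p=p, az=az, alt=alt, pen_down=pen_down,
        sample_rate_hz=sample_rate_hz,
    )


def cohort_seeds(config: CohortConfig) -> list[int]:
    """Per-subject simulation seeds spawned from the cohort seed."""
    ss = np.random.SeedSequence(config.seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(config.n_hc + config.n_ad)]


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[PenStream]:
    """Generate the labeled cohort (HC first, then AD), deterministically.

    Per-subject seeds are spawned from the cohort seed, so subject k's
    stream does not depend on cohort size or on the other subjects.
    """
    seeds = cohort_seeds(config)
    profile_ad = config.ad_profile
    streams = []
    for i in range(config.n_hc):
        streams.append(
            generate_subject(
                config.hc_profile, seeds[i], subject_id=f"HC{i + 1:03d}", label="HC",
                sample_rate_hz=config.sample_rate_hz,
            )
        )
    for j in range(config.n_ad):
        streams.append(
            generate_subject(
                profile_ad, seeds[config.n_hc + j], subject_id=f"AD{j + 1:03d}", label="AD",
                sample_rate_hz=config.sample_rate_hz,
            )
        )
    return streams
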