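import numpy as np
import pytest

from spiralad import PenStream, SubjectProfile, generate_subject


def random_stream(rng: np.random.Generator, n: int | None = None, label: str = "unknown") -> PenStream:
    """A small random but valid stream on the 125 Hz grid."""
    n = n or int(rng.integers(3, 40))
    pen_down = rng.random(n) < 0.8
    p = np.where(pen_down, rng.uniform(0, 1000, n), 0.0)
    return PenStream(
        subject_id=f"S{rng.integers(0, 10**6)}",
        label=label,
        t=np.arange(n) / 125.0,
        x=rng.normal(0, 50, n),
        y=rng.normal(0, 50, n),
        p=p,
        az=rng.uniform(0, 360, n) % 360.0,
        alt=rng.uniform(0, 90, n),
        pen_down=pen_down,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def hc_stream():
    return generate_subject(SubjectProfile(), seed=7, subject_id="HC900", label="HC")
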