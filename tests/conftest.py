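from __future__ import annotations

import pytest

from dresstrack.model import DetectionConfig, Garment, MarkerObservation, load_layout


@pytest.fixture(scope="session")
def config() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture(scope="session")
def shirt_layout():
    return load_layout(Garment.SHIRT)


@pytest.fixture(scope="session")
def pants_layout():
    return load_layout(Garment.PANTS)


def make_obs(marker_id: int, t: float, x: float = 0.5, y: float = 0.5,
             angle: float = 0.0) -> MarkerObservation:
    return MarkerObservation(marker_id=marker_id, x=x, y=y, angle=angle, t=t)


def steady_stream(marker_id: int, t0: float, t1: float, fps: float = 15.0,
                  x: float = 0.5, y: float = 0.5) -> list[MarkerObservation]:
    """Continuous sightings of one marker over [t0, t1] on the frame grid."""
    out = []
    k = 0
    period = 1.0 / fps
    while t0 + k * period <= t1 + 1e-9:
        out.append(make_obs(marker_id, round(t0 + k * period, 6), x=x, y=y))
        k += 1
    return out
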