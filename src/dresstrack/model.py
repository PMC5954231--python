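"""Domain vocabulary for fiducial-marker dressing-state tracking.

A camera system watches printed fiducial markers sewn onto a shirt and a
pair of pants while a person dresses.  Each sighting of a marker is a
:class:`MarkerObservation` (ID, normalized position, orientation, time).
Garment layouts map body regions (front, back, inside, left/right limb,
velcro closure) to the marker IDs attached there; the detection engine
reasons purely over these region sets plus the numeric thresholds in
:class:`DetectionConfig`.

Coordinates are normalized camera coordinates: origin at the top-left,
x rightward, y downward, both in [0, 1].  Orientation angle is carried in
the data model but no identification rule consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class Garment(str, Enum):
    """The two tracked clothing items."""

    SHIRT = "shirt"
    PANTS = "pants"


class Region(str, Enum):
    """Marker-bearing garment regions.

    Every region belongs to exactly one garment; the mapping from region to
    marker IDs lives in the packaged :class:`MarkerLayout` files.
    """

    SHIRT_FRONT = "shirt_front"
    SHIRT_BACK = "shirt_back"
    SHIRT_INSIDE_CENTER = "shirt_inside_center"
    SHIRT_INSIDE_SIDE = "shirt_inside_side"
    SHIRT_FRONT_RIGHT = "shirt_front_right"
    SHIRT_FRONT_LEFT = "shirt_front_left"
    SHIRT_VELCRO = "shirt_velcro"
    PANTS_BACK = "pants_back"
    PANTS_INSIDE_FRONT = "pants_inside_front"
    PANTS_INSIDE_BACK = "pants_inside_back"
    PANTS_LOW_LEFT = "pants_low_left"
    PANTS_LOW_RIGHT = "pants_low_right"
    PANTS_UPPER_FRONT = "pants_upper_front"

    @property
    def garment(self) -> Garment:
        return Garment.SHIRT if self.value.startswith("shirt") else Garment.PANTS


class DetectionLabel(str, Enum):
    """The nine dressing-state detection codes.

    F front, B back, I inside-out, R right limb worn, L left limb worn,
    A both arms worn, M velcro misaligned, p partial dressing, C correctly
    complete.  F, A and M are shirt-only.
    """

    FRONT = "F"
    BACK = "B"
    INSIDE = "I"
    RIGHT = "R"
    LEFT = "L"
    BOTH_ARMS = "A"
    MISALIGNED = "M"
    PARTIAL = "p"
    COMPLETE = "C"


#: Fixed precedence used to order detections emitted at one timestamp.
LABEL_PRECEDENCE: tuple[DetectionLabel, ...] = (
    DetectionLabel.FRONT,
    DetectionLabel.BACK,
    DetectionLabel.INSIDE,
    DetectionLabel.RIGHT,
    DetectionLabel.LEFT,
    DetectionLabel.BOTH_ARMS,
    DetectionLabel.MISALIGNED,
    DetectionLabel.PARTIAL,
    DetectionLabel.COMPLETE,
)

PRECEDENCE_INDEX: dict[DetectionLabel, int] = {
    lab: i for i, lab in enumerate(LABEL_PRECEDENCE)
}

SHIRT_LABELS: frozenset[DetectionLabel] = frozenset(LABEL_PRECEDENCE)
PANTS_LABELS: frozenset[DetectionLabel] = frozenset(
    {
        DetectionLabel.BACK,
        DetectionLabel.INSIDE,
        DetectionLabel.RIGHT,
        DetectionLabel.LEFT,
        DetectionLabel.PARTIAL,
        DetectionLabel.COMPLETE,
    }
)


def labels_for(garment: Garment) -> frozenset[DetectionLabel]:
    """Legal detection labels for a garment (pants never emit F/A/M)."""
    return SHIRT_LABELS if garment is Garment.SHIRT else PANTS_LABELS


@dataclass(frozen=True, slots=True)
class MarkerObservation:
    """One time-stamped sighting of one fiducial marker.

    Attributes
    ----------
    marker_id : int
        Fiducial symbol ID (>= 0).
    x, y : float
        Normalized camera position in [0, 1].
    angle : float
        Orientation in degrees, [0, 360); retained but unused by the rules.
    t : float
        Seconds from stream start (>= 0).
    """

    marker_id: int
    x: float
    y: float
    angle: float
    t: float

    def invariant_violation(self) -> str | None:
        """Return a message describing the first violated field invariant, or None."""
        if self.marker_id < 0:
            return f"marker_id must be >= 0, got {self.marker_id}"
        if not 0.0 <= self.x <= 1.0:
            return f"x out of range [0,1]: {self.x}"
        if not 0.0 <= self.y <= 1.0:
            return f"y out of range [0,1]: {self.y}"
        if self.t < 0:
            return f"t must be >= 0, got {self.t}"
        return None


@dataclass(frozen=True)
class MarkerLayout:
    """Mapping from a garment's regions to the marker IDs attached there."""

    garment: Garment
    region_markers: Mapping[Region, frozenset[int]]
    velcro_pairs: tuple[tuple[int, int], ...]

    def all_markers(self) -> frozenset[int]:
        out: set[int] = set()
        for ids in self.region_markers.values():
            out |= ids
        return frozenset(out)

    def markers(self, region: Region) -> frozenset[int]:
        return self.region_markers.get(region, frozenset())


class DetectionConfig(BaseModel):
    """Numeric thresholds of the identification rules.

    Parameters
    ----------
    persist_s :
        Seconds a region must be continuously visible before its detection
        fires (debounce against transient glimpses).  Default 2.0.
    partial_timeout_s :
        Seconds of one-sided limb visibility (with the opposite side absent)
        before partial dressing is raised.  Default 5.0.
    y_align_max, x_align_max :
        Velcro alignment thresholds on absolute coordinate differences of the
        paired closure markers (0.05 in y, 0.18 in x).
    frame_rate_hz :
        Sampling rate of the observation stream; a configuration default, not
        a property of the rules.
    refractory_s :
        Minimum gap between repeated identical detection labels.
    gap_tolerance_s :
        Maximum inter-sighting gap that still counts as continuous
        visibility; defaults to two frame periods.
    """

    model_config = ConfigDict(frozen=True)

    persist_s: float = 2.0
    partial_timeout_s: float = 5.0
    y_align_max: float = 0.05
    x_align_max: float = 0.18
    frame_rate_hz: float = 15.0
    refractory_s: float = 1.0
    gap_tolerance_s: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "DetectionConfig":
        for name in ("persist_s", "partial_timeout_s", "y_align_max",
                     "x_align_max", "frame_rate_hz", "refractory_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.gap_tolerance_s is not None and self.gap_tolerance_s <= 0:
            raise ValueError("gap_tolerance_s must be strictly positive")
        if not self.persist_s < self.partial_timeout_s:
            raise ValueError("persist_s must be < partial_timeout_s")
        return self

    @property
    def gap_tolerance(self) -> float:
        """Effective run-continuity tolerance (two frame periods by default)."""
        if self.gap_tolerance_s is not None:
            return self.gap_tolerance_s
        return 2.0 / self.frame_rate_hz

    @property
    def frame_period(self) -> float:
        return 1.0 / self.frame_rate_hz

    @classmethod
    def conservative(cls, **overrides) -> "DetectionConfig":
        """Preset with the longer 3-second persistence window.

        The deployed prototype's field observations favoured a 3 s debounce;
        the 2 s value from the rule table remains the default.
        """
        overrides.setdefault("persist_s", 3.0)
        return cls(**overrides)


def _load_layout_file(name: str) -> MarkerLayout:
    text = resources.files("dresstrack.data").joinpath(name).read_text()
    raw = yaml.safe_load(text)
    garment = Garment(raw["garment"])
    region_markers: dict[Region, frozenset[int]] = {}
    for region_name, ids in raw["regions"].items():
        region = Region(region_name)
        if region.garment is not garment:
            raise ValueError(f"region {region_name} does not belong to {garment.value}")
        region_markers[region] = frozenset(int(i) for i in ids)
    pairs = tuple(tuple(int(i) for i in pair) for pair in raw.get("velcro_pairs", []))
    return MarkerLayout(garment=garment, region_markers=region_markers, velcro_pairs=pairs)


@lru_cache(maxsize=None)
def load_layout(garment: Garment | str) -> MarkerLayout:
    """Load the packaged marker layout for ``garment``.

    Deterministic and side-effect free; repeated calls return the same
    (immutable) layout object.
    """
    try:
        garment = Garment(garment)
    except ValueError:
        legal = ", ".join(g.value for g in Garment)
        raise ValueError(f"unknown garment {garment!r}; legal values: {legal}") from None
    return _load_layout_file(f"{garment.value}.yaml")


def regions_of(marker_id: int, layout: MarkerLayout) -> frozenset[Region]:
    """Every region of ``layout`` whose marker set contains ``marker_id``.

    Unknown marker IDs yield the empty set — a live camera sees spurious
    IDs, so they are ignored, never an error.
    """
    return frozenset(
        region for region, ids in layout.region_markers.items() if marker_id in ids
    )


def validate_stream(
    observations: Iterable[MarkerObservation],
) -> list[MarkerObservation]:
    """Validate, time-sort and deduplicate an observation stream.

    Records sharing identical ``(t, marker_id)`` collapse to the first
    occurrence.  Field-invariant violations are rejected with the offending
    record's index in the input order.  Idempotent.
    """
    obs = list(observations)
    for i, o in enumerate(obs):
        msg = o.invariant_violation()
        if msg is not None:
            raise ValueError(f"invalid observation at index {i}: {msg}")
    obs.sort(key=lambda o: (o.t, o.marker_id))
    out: list[MarkerObservation] = []
    seen: set[tuple[float, int]] = set()
    for o in obs:
        key = (o.t, o.marker_id)
        if key in seen:
            continue
        seen.add(key)
        out.append(o)
    return out


def frames_of(
    observations: Sequence[MarkerObservation],
) -> list[tuple[float, list[MarkerObservation]]]:
    """Group a time-sorted stream into frames of equal timestamp."""
    frames: list[tuple[float, list[MarkerObservation]]] = []
    for o in observations:
        if frames and frames[-1][0] == o.t:
            frames[-1][1].append(o)
        else:
            frames.append((o.t, [o]))
    return frames
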