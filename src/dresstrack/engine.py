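"""Temporal rule engine: marker observation streams -> dressing-state events.

The engine replays a validated stream frame by frame, maintains a per-marker
visibility run (``continuous_since`` / ``last_seen``), and evaluates the
garment's identification rules at every frame:

* region rules (F/B/I/R/L) fire when any marker of the region has been
  continuously visible for the persistence window (debounce);
* A fires when one right-side and one left-side marker are simultaneously
  persistence-qualified;
* M/C for the shirt compare absolute coordinate differences of the paired
  velcro closure markers against the alignment thresholds;
* C for the pants requires *all* upper-front markers to be
  persistence-qualified;
* p (partial dressing) fires when one limb side has been visible while the
  opposite side has had no sighting for the partial timeout.

Emission is edge-triggered: a label is emitted at the first instant its rule
becomes satisfied, repeats within the refractory window are suppressed, and
simultaneous detections are ordered by the fixed precedence
F < B < I < R < L < A < M < p < C.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import (
    DetectionConfig,
    DetectionLabel,
    Garment,
    MarkerLayout,
    MarkerObservation,
    PRECEDENCE_INDEX,
    Region,
    frames_of,
    labels_for,
    load_layout,
    validate_stream,
)

# Comparison slack sized to absorb 6-decimal timestamp rounding in replayed
# stream files; far below any rule timescale.
_EPS = 1e-6

#: Velcro closure marker IDs, paired left/right across the shirt opening.
VELCRO_PAIRS: tuple[tuple[int, int], ...] = ((208, 209), (211, 212))
VELCRO_IDS: frozenset[int] = frozenset({208, 209, 211, 212})

#: Limb "side" regions used by R/L and the partial rule.
SIDE_REGIONS: dict[Garment, tuple[Region, Region]] = {
    Garment.SHIRT: (Region.SHIRT_FRONT_RIGHT, Region.SHIRT_FRONT_LEFT),
    Garment.PANTS: (Region.PANTS_LOW_RIGHT, Region.PANTS_LOW_LEFT),
}

INSIDE_REGIONS: dict[Garment, tuple[Region, ...]] = {
    Garment.SHIRT: (Region.SHIRT_INSIDE_CENTER, Region.SHIRT_INSIDE_SIDE),
    Garment.PANTS: (Region.PANTS_INSIDE_FRONT, Region.PANTS_INSIDE_BACK),
}

BACK_REGION: dict[Garment, Region] = {
    Garment.SHIRT: Region.SHIRT_BACK,
    Garment.PANTS: Region.PANTS_BACK,
}


@dataclass
class MarkerRun:
    """Current unbroken visibility run of one marker."""

    continuous_since: float
    last_seen: float
    last_position: tuple[float, float]


@dataclass
class VisibilityState:
    """Per-marker visibility bookkeeping for the persistence clocks.

    A run is unbroken while consecutive sightings are at most
    ``gap_tolerance`` apart; a longer gap restarts the run.
    """

    gap_tolerance: float
    runs: dict[int, MarkerRun] = field(default_factory=dict)
    clock: float = float("-inf")

    def absorb(self, t: float, frame: Iterable[MarkerObservation]) -> None:
        """Absorb one frame of observations (mutating)."""
        if t < self.clock - _EPS:
            raise ValueError(f"time regression: frame at t={t} after t={self.clock}")
        self.clock = max(self.clock, t)
        for o in frame:
            if abs(o.t - t) > _EPS:
                raise ValueError("all observations in a frame must share one timestamp")
            run = self.runs.get(o.marker_id)
            pos = (o.x, o.y)
            if run is None or t - run.last_seen > self.gap_tolerance + _EPS:
                self.runs[o.marker_id] = MarkerRun(t, t, pos)
            else:
                run.last_seen = t
                run.last_position = pos

    # -- queries ---------------------------------------------------------

    def recent(self, marker_id: int, t: float) -> bool:
        """Marker sighted within the gap tolerance of ``t``."""
        run = self.runs.get(marker_id)
        return run is not None and t - run.last_seen <= self.gap_tolerance + _EPS

    def qualified(self, marker_id: int, t: float, persist_s: float) -> bool:
        """Marker recent and its unbroken run at least ``persist_s`` long."""
        run = self.runs.get(marker_id)
        return (
            run is not None
            and t - run.last_seen <= self.gap_tolerance + _EPS
            and t - run.continuous_since >= persist_s - _EPS
        )

    def run_length(self, marker_id: int, t: float) -> float:
        """Length of the current run if recent, else 0."""
        run = self.runs.get(marker_id)
        if run is None or t - run.last_seen > self.gap_tolerance + _EPS:
            return 0.0
        return t - run.continuous_since

    def last_seen(self, marker_id: int) -> float | None:
        run = self.runs.get(marker_id)
        return None if run is None else run.last_seen

    def recent_positions(self, marker_ids: Iterable[int], t: float) -> dict[int, tuple[float, float]]:
        """Most recent position of each marker sighted within the gap window."""
        out: dict[int, tuple[float, float]] = {}
        for m in marker_ids:
            run = self.runs.get(m)
            if run is not None and t - run.last_seen <= self.gap_tolerance + _EPS:
                out[m] = run.last_position
        return out


def update_visibility(
    state: VisibilityState, frame: Iterable[MarkerObservation]
) -> VisibilityState:
    """Functional visibility update: returns a new state with the frame absorbed.

    All observations in ``frame`` must share one timestamp not earlier than
    any timestamp already absorbed.
    """
    frame = list(frame)
    new = copy.deepcopy(state)
    if frame:
        new.absorb(frame[0].t, frame)
    return new


def region_visible(
    state: VisibilityState,
    region: Region,
    layout: MarkerLayout,
    t: float,
    persist_s: float,
) -> bool:
    """True iff some marker of ``region`` is persistence-qualified at ``t``."""
    return any(state.qualified(m, t, persist_s) for m in layout.markers(region))


def _velcro_diffs(
    positions: Mapping[int, tuple[float, float]]
) -> tuple[list[float], list[float]] | None:
    """Per-pair |dx| and |dy| of the velcro markers, or None if any is missing."""
    if not VELCRO_IDS <= set(positions):
        return None
    dxs, dys = [], []
    for a, b in VELCRO_PAIRS:
        (xa, ya), (xb, yb) = positions[a], positions[b]
        dxs.append(abs(xa - xb))
        dys.append(abs(ya - yb))
    return dxs, dys


def misaligned(
    positions: Mapping[int, tuple[float, float]], config: DetectionConfig
) -> bool | None:
    """Velcro unevenly fastened: any pairwise |dy| > 0.05 or |dx| > 0.18.

    Returns None ("cannot assess") when any of the four closure markers has
    no position, which is distinct from an aligned False.
    """
    diffs = _velcro_diffs(positions)
    if diffs is None:
        return None
    dxs, dys = diffs
    return any(dy > config.y_align_max for dy in dys) or any(
        dx > config.x_align_max for dx in dxs
    )


def shirt_complete(
    positions: Mapping[int, tuple[float, float]], config: DetectionConfig
) -> bool | None:
    """Shirt closed correctly: every pairwise |dy| and |dx| within threshold.

    Equality at a threshold counts as complete, so misaligned() and
    shirt_complete() partition the determinate cases.  Returns None when a
    closure marker is missing.
    """
    diffs = _velcro_diffs(positions)
    if diffs is None:
        return None
    dxs, dys = diffs
    return all(dy <= config.y_align_max for dy in dys) and all(
        dx <= config.x_align_max for dx in dxs
    )


def pants_complete(
    state: VisibilityState, layout: MarkerLayout, t: float, config: DetectionConfig
) -> bool:
    """Pants worn correctly: *all* upper-front markers persistence-qualified."""
    uppers = layout.markers(Region.PANTS_UPPER_FRONT)
    return bool(uppers) and all(
        state.qualified(m, t, config.persist_s) for m in uppers
    )


def _side_state(
    state: VisibilityState, layout: MarkerLayout, region: Region, t: float, config: DetectionConfig
) -> tuple[frozenset[int], float, float | None]:
    """(qualified markers, longest current run, most recent sighting) of a side."""
    ids = layout.markers(region)
    qualified = frozenset(m for m in ids if state.qualified(m, t, config.persist_s))
    longest = max((state.run_length(m, t) for m in ids), default=0.0)
    seen = [state.last_seen(m) for m in ids]
    seen = [s for s in seen if s is not None]
    return qualified, longest, (max(seen) if seen else None)


def partial_check(
    state: VisibilityState, layout: MarkerLayout, t: float, config: DetectionConfig
) -> bool:
    """One limb side visible >= partial_timeout_s with the other side absent.

    "Absent" is the strict reading: no sighting of the opposite side for at
    least ``partial_timeout_s`` (a never-seen side counts as absent).
    """
    sat, _ = _partial_state(state, layout, t, config)
    return sat


def _partial_state(
    state: VisibilityState, layout: MarkerLayout, t: float, config: DetectionConfig
) -> tuple[bool, tuple[frozenset[int], Region] | None]:
    right, left = SIDE_REGIONS[layout.garment]
    for visible, absent in ((right, left), (left, right)):
        vis_q, vis_run, _ = _side_state(state, layout, visible, t, config)
        if not vis_q or vis_run < config.partial_timeout_s - _EPS:
            continue
        _, _, other_seen = _side_state(state, layout, absent, t, config)
        if other_seen is None or t - other_seen >= config.partial_timeout_s - _EPS:
            return True, (vis_q, absent)
    return False, None


@dataclass(frozen=True)
class DetectionEvent:
    """A labeled dressing-state detection with its marker evidence."""

    label: DetectionLabel
    garment: Garment
    t: float
    evidence: frozenset[int]

    def __post_init__(self) -> None:
        if self.label not in labels_for(self.garment):
            raise ValueError(
                f"label {self.label.value} is not legal for {self.garment.value}"
            )


def _rule_status(
    label: DetectionLabel,
    state: VisibilityState,
    layout: MarkerLayout,
    t: float,
    config: DetectionConfig,
) -> tuple[bool, frozenset[int], Region | None]:
    """(satisfied, evidence, partial-absent-side) of one rule at instant t."""
    g = layout.garment
    persist = config.persist_s

    def qualified_in(*regions: Region) -> frozenset[int]:
        out: set[int] = set()
        for r in regions:
            out |= {m for m in layout.markers(r) if state.qualified(m, t, persist)}
        return frozenset(out)

    if label is DetectionLabel.FRONT:
        ev = qualified_in(Region.SHIRT_FRONT)
        return bool(ev), ev, None
    if label is DetectionLabel.BACK:
        ev = qualified_in(BACK_REGION[g])
        return bool(ev), ev, None
    if label is DetectionLabel.INSIDE:
        ev = qualified_in(*INSIDE_REGIONS[g])
        return bool(ev), ev, None
    if label in (DetectionLabel.RIGHT, DetectionLabel.LEFT):
        right, left = SIDE_REGIONS[g]
        ev = qualified_in(right if label is DetectionLabel.RIGHT else left)
        return bool(ev), ev, None
    if label is DetectionLabel.BOTH_ARMS:
        right, left = SIDE_REGIONS[g]
        ev_r, ev_l = qualified_in(right), qualified_in(left)
        if ev_r and ev_l:
            return True, ev_r | ev_l, None
        return False, frozenset(), None
    if label is DetectionLabel.MISALIGNED:
        positions = state.recent_positions(VELCRO_IDS, t)
        mis = misaligned(positions, config)
        if mis:
            return True, frozenset(positions), None
        return False, frozenset(), None
    if label is DetectionLabel.PARTIAL:
        sat, info = _partial_state(state, layout, t, config)
        if sat:
            assert info is not None
            return True, info[0], info[1]
        return False, frozenset(), None
    if label is DetectionLabel.COMPLETE:
        if g is Garment.PANTS:
            if pants_complete(state, layout, t, config):
                return True, layout.markers(Region.PANTS_UPPER_FRONT), None
            return False, frozenset(), None
        # Shirt completion: the four closure markers must themselves pass the
        # debounce before their geometry is trusted.
        if all(state.qualified(m, t, persist) for m in VELCRO_IDS):
            positions = state.recent_positions(VELCRO_IDS, t)
            if shirt_complete(positions, config):
                return True, VELCRO_IDS, None
        return False, frozenset(), None
    raise AssertionError(f"unhandled label {label}")  # pragma: no cover


def run_detection(
    stream: Sequence[MarkerObservation],
    garment: Garment | str,
    config: DetectionConfig | None = None,
) -> list[DetectionEvent]:
    """Run the full rule set over an observation stream.

    Returns time-ordered :class:`DetectionEvent`s; events sharing a timestamp
    are ordered by the fixed label precedence.  The stream is validated
    (sorted/deduplicated) defensively.
    """
    config = config or DetectionConfig()
    layout = load_layout(garment)
    garment = layout.garment
    legal = [lab for lab in PRECEDENCE_INDEX if lab in labels_for(garment)]
    legal.sort(key=PRECEDENCE_INDEX.__getitem__)

    state = VisibilityState(gap_tolerance=config.gap_tolerance)
    prev_sat: dict[DetectionLabel, bool] = {lab: False for lab in legal}
    last_emit: dict[DetectionLabel, float] = {}
    p_armed = True
    p_rearm_region: Region | None = None

    events: list[DetectionEvent] = []
    for t, frame in frames_of(validate_stream(stream)):
        state.absorb(t, frame)
        # Re-arm partial once the previously absent side shows up again.
        if p_rearm_region is not None:
            sighted = {o.marker_id for o in frame}
            if sighted & layout.markers(p_rearm_region):
                p_armed = True
                p_rearm_region = None
        for label in legal:
            sat, evidence, absent_side = _rule_status(label, state, layout, t, config)
            if sat and not prev_sat[label]:
                refractory_ok = (
                    label not in last_emit
                    or t - last_emit[label] >= config.refractory_s - _EPS
                )
                armed = p_armed if label is DetectionLabel.PARTIAL else True
                if refractory_ok and armed:
                    events.append(
                        DetectionEvent(label=label, garment=garment, t=t, evidence=evidence)
                    )
                    last_emit[label] = t
                    if label is DetectionLabel.PARTIAL:
                        p_armed = False
                        p_rearm_region = absent_side
            prev_sat[label] = sat
    return events
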