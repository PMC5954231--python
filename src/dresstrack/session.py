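"""Dressing-session orchestration state machine.

Drives one dressing session over abstract input events: a motion-sensor
presence signal, drawer open/close switches, an RFID tag leaving its drawer
(which arms garment tracking), dressing-state detections from the rule
engine, and a unitless stress level.  It produces the prompt/light
transcript and caregiver alerts.

Two prompting modes exist: *continuous* narrates every step; *independent*
emits corrective prompts only (no praise or progress narration), so a
capable dresser is left alone while errors still trigger guidance.  Stress
follows a two-threshold escalation: crossing the soothe level triggers a
calming intervention once per episode; if stress keeps rising past the alert
level the caregiver is notified; the episode resets when stress falls back
below the soothe level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .engine import DetectionEvent
from .model import DetectionLabel, Garment

logger = logging.getLogger(__name__)

PROGRESS_LABELS = frozenset(
    {DetectionLabel.RIGHT, DetectionLabel.LEFT, DetectionLabel.BOTH_ARMS, DetectionLabel.COMPLETE}
)
CORRECTIVE_LABELS = frozenset(
    {DetectionLabel.BACK, DetectionLabel.INSIDE, DetectionLabel.MISALIGNED, DetectionLabel.PARTIAL}
)


class Mode(str, Enum):
    CONTINUOUS = "continuous"
    INDEPENDENT = "independent"


class EventKind(str, Enum):
    PRESENCE = "presence"
    DRAWER_OPEN = "drawer_open"
    DRAWER_CLOSE = "drawer_close"
    RFID_REMOVED = "rfid_removed"
    DETECTION = "detection"
    STRESS = "stress"


@dataclass(frozen=True)
class SessionEvent:
    """One time-stamped session input."""

    t: float
    kind: EventKind
    drawer: int | None = None
    detection: DetectionEvent | None = None
    level: float | None = None

    # -- constructors ----------------------------------------------------
    @classmethod
    def presence(cls, t: float) -> "SessionEvent":
        return cls(t, EventKind.PRESENCE)

    @classmethod
    def drawer_open(cls, t: float, drawer: int) -> "SessionEvent":
        return cls(t, EventKind.DRAWER_OPEN, drawer=drawer)

    @classmethod
    def drawer_close(cls, t: float, drawer: int) -> "SessionEvent":
        return cls(t, EventKind.DRAWER_CLOSE, drawer=drawer)

    @classmethod
    def rfid_removed(cls, t: float, drawer: int) -> "SessionEvent":
        return cls(t, EventKind.RFID_REMOVED, drawer=drawer)

    @classmethod
    def from_detection(cls, t: float, detection: DetectionEvent) -> "SessionEvent":
        return cls(t, EventKind.DETECTION, detection=detection)

    @classmethod
    def stress(cls, t: float, level: float) -> "SessionEvent":
        return cls(t, EventKind.STRESS, level=level)


class SessionConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    mode: Mode = Mode.CONTINUOUS
    garment_order: tuple[tuple[int, Garment], ...] = (
        (1, Garment.SHIRT),
        (2, Garment.PANTS),
    )
    stress_soothe_level: float = 0.5
    stress_alert_level: float = 0.8
    stall_s: float = 10.0
    max_corrections: int = 3

    @model_validator(mode="after")
    def _check(self) -> "SessionConfig":
        if not self.stress_alert_level > self.stress_soothe_level:
            raise ValueError("stress_alert_level must exceed stress_soothe_level")
        if self.stall_s <= 0 or self.max_corrections <= 0:
            raise ValueError("stall_s and max_corrections must be positive")
        if not self.garment_order:
            raise ValueError("garment_order must not be empty")
        return self

    @property
    def drawers(self) -> tuple[int, ...]:
        return tuple(d for d, _ in self.garment_order)


@dataclass(frozen=True)
class Prompt:
    t: float
    prompt_id: str
    lights: tuple[tuple[int, str], ...]  # (drawer, "green"|"red") sorted by drawer


@dataclass(frozen=True)
class Alert:
    t: float
    kind: str  # soothe | caregiver_notify | completed


@dataclass
class SessionOutput:
    prompts: list[Prompt] = field(default_factory=list)
    alerts: list[Alert] = field(default_factory=list)


@dataclass(frozen=True)
class SessionState:
    """Immutable session state; :func:`step` returns an updated copy."""

    clock: float = float("-inf")
    started: bool = False
    finished: bool = False
    garment_idx: int = 0
    tracking: bool = False
    garment_complete: bool = False
    corrections: int = 0
    last_progress_t: float = 0.0
    motivated: bool = False
    stress_soothed: bool = False
    stress_notified: bool = False
    latest_stress: float = 0.0


def _lights(config: SessionConfig, state: SessionState) -> tuple[tuple[int, str], ...]:
    """Current drawer light assignment: active drawer green, rest red."""
    if not state.started or state.finished:
        return tuple((d, "red") for d in config.drawers)
    active = config.garment_order[state.garment_idx][0]
    return tuple(
        (d, "green" if d == active else "red") for d in config.drawers
    )


def _stress_step(
    soothed: bool, notified: bool, level: float, config: SessionConfig
) -> tuple[bool, bool, list[str]]:
    """One stress sample through the escalation episode algebra."""
    alerts: list[str] = []
    if level < config.stress_soothe_level:
        return False, False, alerts  # episode reset
    if not soothed:
        alerts.append("soothe")
        soothed = True
    if soothed and level > config.stress_alert_level and not notified:
        alerts.append("caregiver_notify")
        notified = True
    return soothed, notified, alerts


def escalate(
    stress_series: Sequence[tuple[float, float]], config: SessionConfig
) -> list[Alert]:
    """Run the soothe/notify escalation over a time-ordered stress series."""
    soothed = notified = False
    out: list[Alert] = []
    for t, level in stress_series:
        soothed, notified, kinds = _stress_step(soothed, notified, level, config)
        out.extend(Alert(t, k) for k in kinds)
    return out


def stuck_check(recent: Sequence[SessionEvent], config: SessionConfig) -> bool:
    """Is the dresser stuck, given a recent event window?

    True iff no progress-class detection (R/L/A/C) for at least ``stall_s``
    while the latest stress sample is at or above the soothe level, or the
    window already contains ``max_corrections`` corrective detections.
    """
    if not recent:
        return False
    window_start = recent[0].t
    window_end = recent[-1].t
    last_progress = window_start
    latest_stress = 0.0
    corrective = 0
    for e in recent:
        if e.kind is EventKind.DETECTION and e.detection is not None:
            if e.detection.label in PROGRESS_LABELS:
                last_progress = e.t
            elif e.detection.label in CORRECTIVE_LABELS:
                corrective += 1
        elif e.kind is EventKind.STRESS and e.level is not None:
            latest_stress = e.level
    stalled = (window_end - last_progress) >= config.stall_s and (
        latest_stress >= config.stress_soothe_level
    )
    return stalled or corrective >= config.max_corrections


def step(
    state: SessionState, event: SessionEvent, config: SessionConfig
) -> tuple[SessionState, list[Prompt], list[Alert]]:
    """Pure transition: same (state, event, config) always yields the same
    outputs.  Events arriving before presence are ignored with a warning
    (hardware can misfire)."""
    if event.t < state.clock:
        raise ValueError(f"event at t={event.t} precedes session clock {state.clock}")
    prompts: list[Prompt] = []
    alerts: list[Alert] = []
    t = event.t
    s = replace(state, clock=t)

    if not s.started:
        if event.kind is not EventKind.PRESENCE:
            logger.warning("ignoring %s before presence at t=%s", event.kind.value, t)
            return s, prompts, alerts
        s = replace(s, started=True, last_progress_t=t)
        drawer = config.garment_order[0][0]
        prompts.append(Prompt(t, f"open_drawer_{drawer}", _lights(config, s)))
        return s, prompts, alerts

    if s.finished:
        return s, prompts, alerts

    active_drawer, active_garment = config.garment_order[s.garment_idx]

    if event.kind is EventKind.DRAWER_OPEN:
        if event.drawer != active_drawer:
            prompts.append(
                Prompt(t, f"close_wrong_drawer_{event.drawer}", _lights(config, s))
            )
        elif config.mode is Mode.CONTINUOUS:
            prompts.append(
                Prompt(t, f"remove_{active_garment.value}", _lights(config, s))
            )
    elif event.kind is EventKind.RFID_REMOVED:
        if event.drawer == active_drawer:
            s = replace(s, tracking=True)
            if config.mode is Mode.CONTINUOUS:
                prompts.append(
                    Prompt(t, f"begin_{active_garment.value}", _lights(config, s))
                )
    elif event.kind is EventKind.DETECTION:
        det = event.detection
        if det is None or not s.tracking:
            logger.warning("ignoring detection before tracking armed at t=%s", t)
        elif det.label in CORRECTIVE_LABELS:
            s = replace(s, corrections=s.corrections + 1)
            prompts.append(Prompt(t, f"correct_{det.label.value}", _lights(config, s)))
        elif det.label is DetectionLabel.COMPLETE:
            s = replace(s, garment_complete=True, last_progress_t=t, motivated=False)
            if config.mode is Mode.CONTINUOUS:
                prompts.append(Prompt(t, "praise_complete", _lights(config, s)))
            prompts.append(Prompt(t, f"close_drawer_{active_drawer}", _lights(config, s)))
        elif det.label in PROGRESS_LABELS:
            s = replace(s, last_progress_t=t, motivated=False)
            if config.mode is Mode.CONTINUOUS:
                prompts.append(
                    Prompt(t, f"progress_{det.label.value}", _lights(config, s))
                )
    elif event.kind is EventKind.DRAWER_CLOSE:
        if event.drawer == active_drawer and s.garment_complete:
            if s.garment_idx + 1 >= len(config.garment_order):
                s = replace(s, finished=True)
                alerts.append(Alert(t, "completed"))
            else:
                s = replace(
                    s,
                    garment_idx=s.garment_idx + 1,
                    tracking=False,
                    garment_complete=False,
                    corrections=0,
                    last_progress_t=t,
                    motivated=False,
                )
                next_drawer = config.garment_order[s.garment_idx][0]
                prompts.append(
                    Prompt(t, f"open_drawer_{next_drawer}", _lights(config, s))
                )
    elif event.kind is EventKind.STRESS:
        level = float(event.level or 0.0)
        soothed, notified, kinds = _stress_step(
            s.stress_soothed, s.stress_notified, level, config
        )
        s = replace(
            s, stress_soothed=soothed, stress_notified=notified, latest_stress=level
        )
        alerts.extend(Alert(t, k) for k in kinds)

    # Motivational re-engagement when stalled under stress or after repeated
    # corrections; fires once per stall episode (progress re-arms it).
    if not s.finished:
        stalled = (
            t - s.last_progress_t >= config.stall_s
            and s.latest_stress >= config.stress_soothe_level
        )
        if (stalled or s.corrections >= config.max_corrections) and not s.motivated:
            prompts.append(Prompt(t, "motivational", _lights(config, s)))
            s = replace(s, motivated=True)
    return s, prompts, alerts


def run_session(
    events: Iterable[SessionEvent], config: SessionConfig | None = None
) -> SessionOutput:
    """Fold :func:`step` over a time-ordered event log."""
    config = config or SessionConfig()
    state = SessionState()
    out = SessionOutput()
    for event in events:
        state, prompts, alerts = step(state, event, config)
        out.prompts.extend(prompts)
        out.alerts.extend(alerts)
    return out


def output_to_json(output: SessionOutput) -> str:
    """Canonical JSON serialization of a session transcript (byte-stable)."""
    import json

    return json.dumps(
        {
            "prompts": [
                {"t": p.t, "prompt_id": p.prompt_id, "lights": [list(l) for l in p.lights]}
                for p in output.prompts
            ],
            "alerts": [{"t": a.t, "kind": a.kind} for a in output.alerts],
        },
        sort_keys=True,
        separators=(",", ":"),
    )
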