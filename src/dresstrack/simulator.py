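"""Synthetic marker-stream generator for the nine dressing conditions.

Each condition is scripted as a set of piecewise-constant *region
exposures*: a marker is "presented to the camera" over a time interval
anchored at a fixed position, with a small-amplitude bounded random walk
around the anchor.  The noise-free script of every condition is constructed
so the rule engine reproduces exactly that condition's required detection
sequence (first limb, second limb, completion, plus the scripted acted
error) with nothing unexpected.

The noise model layers on the documented real-world failure modes:

* per-frame dropout, growing with camera distance (smaller effective marker
  size at range);
* whole-region fold occlusion for a phase (garment too large);
* transient wrong-region glimpses (back/inside flashes while the garment is
  folded or moved) injected only during the transition phases;
* too-fast donning via a speed multiplier that compresses exposures below
  the persistence window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .engine import VELCRO_IDS
from .evaluation import (
    ALL_CONDITIONS,
    Condition,
    ErrorMode,
    TrialAssignment,
    TrialRoster,
    enumerate_trials,
)
from .model import DetectionConfig, Garment, MarkerObservation, Region


class NoiseModel(BaseModel):
    """Stochastic degradation parameters (defaults: noise off).

    ``base_dropout_p`` is the per-frame probability that a visible marker
    goes unreported; ``distance_dropout_coeff`` adds dropout per unit of
    actor distance; glimpses are transient wrong-region (back/inside)
    sightings during transition phases; ``fold_occlusion_p`` is the chance a
    whole scripted region is occluded for an entire phase.
    """

    model_config = ConfigDict(frozen=True)

    base_dropout_p: float = 0.0
    distance_dropout_coeff: float = 0.0
    glimpse_rate_hz: float = 0.0
    glimpse_duration_s: float = 1.0
    fold_occlusion_p: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "NoiseModel":
        for name in ("base_dropout_p", "fold_occlusion_p"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1]")
        for name in ("distance_dropout_coeff", "glimpse_rate_hz", "glimpse_duration_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self

    @classmethod
    def realistic(cls, **overrides) -> "NoiseModel":
        """A moderately noisy camera: occasional dropouts and glimpses."""
        defaults = dict(
            base_dropout_p=0.05,
            distance_dropout_coeff=0.10,
            glimpse_rate_hz=0.10,
            glimpse_duration_s=1.0,
            fold_occlusion_p=0.05,
        )
        defaults.update(overrides)
        return cls(**defaults)


def dropout_probability(noise: NoiseModel, actor_distance: float) -> float:
    """Per-frame dropout probability at a given camera distance (clamped)."""
    if actor_distance < 0:
        raise ValueError("actor_distance must be >= 0")
    return min(1.0, noise.base_dropout_p + noise.distance_dropout_coeff * actor_distance)


def default_phase_durations(condition: Condition) -> tuple[float, ...]:
    """Per-condition default phase durations (seconds).

    Chosen so that, at the default 2 s persistence / 5 s partial timeout,
    the noise-free script of each condition yields exactly its expected
    detections: pants transitions are kept under the partial timeout except
    in the partial condition's long stall.
    """
    if condition.garment is Garment.SHIRT:
        if condition.error_mode is ErrorMode.PARTIAL:
            return (4.0, 3.0, 6.0, 3.0, 4.0, 6.0)
        return (4.0, 3.0, 4.0, 3.0, 4.0, 6.0)
    if condition.error_mode is ErrorMode.PARTIAL:
        return (4.0, 3.0, 8.0, 3.0, 4.0, 6.0)
    return (4.0, 2.5, 2.0, 3.0, 4.0, 6.0)


class ScenarioSpec(BaseModel):
    """Parameters generating one synthetic trial."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    condition: Condition
    phase_durations_s: tuple[float, float, float, float, float, float] | None = None
    actor_distance: float = 0.0
    dressing_speed: float = 1.0
    terminal_hold_s: float = 3.0

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSpec":
        if self.phase_durations_s is not None and any(
            d <= 0 for d in self.phase_durations_s
        ):
            raise ValueError("phase durations must be positive")
        if self.dressing_speed <= 0:
            raise ValueError("dressing_speed must be > 0")
        if self.actor_distance < 0:
            raise ValueError("actor_distance must be >= 0")
        if self.terminal_hold_s < 0:
            raise ValueError("terminal_hold_s must be >= 0")
        return self

    @property
    def durations(self) -> tuple[float, ...]:
        base = self.phase_durations_s or default_phase_durations(self.condition)
        eff = [d / self.dressing_speed for d in base]
        # The end-of-trial stillness extends the completion phase.
        eff[5] += self.terminal_hold_s / self.dressing_speed
        return tuple(eff)


@dataclass(frozen=True)
class Exposure:
    """One marker presented to the camera over [t_start, t_end)."""

    marker_id: int
    t_start: float
    t_end: float
    anchor: tuple[float, float]
    phase: int
    region: Region | None = None


@dataclass
class SimulatedTrial:
    stream: list[MarkerObservation]
    truth_phases: dict[int, tuple[float, float]]
    truth_condition: Condition
    seed: int


# Representative markers used by the scripts.
_SHIRT_RIGHT, _SHIRT_LEFT, _SHIRT_BACK, _SHIRT_INSIDE = 11, 31, 7, 8
_PANTS_RIGHT, _PANTS_LEFT, _PANTS_BACK, _PANTS_INSIDE = 25, 28, 22, 17
_PANTS_UPPER = (15, 16, 24, 27)

#: Screen anchors for scripted marker positions (normalized coordinates).
_ANCHORS: dict[int, tuple[float, float]] = {
    _SHIRT_RIGHT: (0.40, 0.45),
    _SHIRT_LEFT: (0.60, 0.45),
    _SHIRT_BACK: (0.50, 0.40),
    _SHIRT_INSIDE: (0.50, 0.42),
    9: (0.45, 0.42),
    _PANTS_RIGHT: (0.42, 0.80),
    26: (0.46, 0.80),
    _PANTS_LEFT: (0.58, 0.80),
    29: (0.62, 0.80),
    _PANTS_BACK: (0.50, 0.60),
    _PANTS_INSIDE: (0.50, 0.58),
    19: (0.55, 0.58),
    15: (0.44, 0.50),
    16: (0.48, 0.50),
    24: (0.52, 0.50),
    27: (0.56, 0.50),
}

# Velcro closure geometry: aligned pairs sit 0.05 apart in x and 0.02 in y
# (inside both thresholds even under the +-0.01 position jitter); the
# misaligned script offsets one pair member by 0.10 in y.
_VELCRO_ALIGNED: dict[int, tuple[float, float]] = {
    208: (0.45, 0.50),
    209: (0.50, 0.52),
    211: (0.45, 0.60),
    212: (0.50, 0.62),
}
_VELCRO_MISALIGNED: dict[int, tuple[float, float]] = {
    208: (0.45, 0.50),
    209: (0.50, 0.60),
    211: (0.45, 0.60),
    212: (0.50, 0.62),
}

_BOUNDS = {1: (0, 1), 2: (1, 2), 3: (2, 3), 4: (3, 4), 5: (4, 5), 6: (5, 6)}


def _phase_edges(durations: Sequence[float]) -> list[float]:
    edges = [0.0]
    for d in durations:
        edges.append(edges[-1] + d)
    return edges


def _span_exposures(
    marker: int,
    phase_from: int,
    phase_to: int,
    edges: Sequence[float],
    anchor: tuple[float, float],
) -> list[Exposure]:
    """Contiguous per-phase exposure chunks of one marker."""
    out = []
    for ph in range(phase_from, phase_to + 1):
        a, b = edges[ph - 1], edges[ph]
        out.append(Exposure(marker, a, b, anchor, ph))
    return out


def build_script(spec: ScenarioSpec) -> tuple[list[Exposure], dict[int, tuple[float, float]]]:
    """Noise-free exposure script and truth phase intervals for a condition."""
    cond = spec.condition
    durations = spec.durations
    edges = _phase_edges(durations)
    truth = {i: (edges[i - 1], edges[i]) for i in range(1, 7)}
    exposures: list[Exposure] = []

    if cond.garment is Garment.SHIRT:
        # First limb from phase 2 onward, second from phase 4 onward.
        exposures += _span_exposures(_SHIRT_RIGHT, 2, 6, edges, _ANCHORS[_SHIRT_RIGHT])
        exposures += _span_exposures(_SHIRT_LEFT, 4, 6, edges, _ANCHORS[_SHIRT_LEFT])
        if cond.error_mode is ErrorMode.BACK_TO_FRONT:
            exposures.append(
                Exposure(_SHIRT_BACK, edges[0], edges[1], _ANCHORS[_SHIRT_BACK], 1)
            )
        elif cond.error_mode is ErrorMode.INSIDE_OUT:
            exposures.append(
                Exposure(_SHIRT_INSIDE, edges[0], edges[1], _ANCHORS[_SHIRT_INSIDE], 1)
            )
        if cond.error_mode is ErrorMode.MISALIGNED:
            # Misaligned closure shown through phase 5, corrected in phase 6.
            for m in sorted(VELCRO_IDS):
                exposures.append(Exposure(m, edges[4], edges[5], _VELCRO_MISALIGNED[m], 5))
                exposures.append(Exposure(m, edges[5], edges[6], _VELCRO_ALIGNED[m], 6))
        else:
            for m in sorted(VELCRO_IDS):
                exposures.append(Exposure(m, edges[5], edges[6], _VELCRO_ALIGNED[m], 6))
        # The shirt-partial stall is simply the opposite side staying absent
        # through the long phase 3; no extra exposures are needed.
    else:
        exposures += _span_exposures(_PANTS_RIGHT, 2, 6, edges, _ANCHORS[_PANTS_RIGHT])
        exposures += _span_exposures(_PANTS_LEFT, 4, 6, edges, _ANCHORS[_PANTS_LEFT])
        if cond.error_mode is ErrorMode.BACK_TO_FRONT:
            exposures.append(
                Exposure(_PANTS_BACK, edges[0], edges[1], _ANCHORS[_PANTS_BACK], 1)
            )
        elif cond.error_mode is ErrorMode.INSIDE_OUT:
            exposures.append(
                Exposure(_PANTS_INSIDE, edges[0], edges[1], _ANCHORS[_PANTS_INSIDE], 1)
            )
        elif cond.error_mode is ErrorMode.PARTIAL:
            # Folds keep the opposite low-leg markers mostly hidden during the
            # one-sided stall, with brief sub-persistence flaps into view that
            # keep the strict 5 s absence clause from ever completing.
            stall_start, stall_end = edges[2], edges[3]
            tg = stall_start + 1.0
            while tg < stall_end - 0.5:
                exposures.append(
                    Exposure(_PANTS_LEFT, tg, tg + 1e-6, _ANCHORS[_PANTS_LEFT], 3)
                )
                tg += 3.0
        for m in _PANTS_UPPER:
            exposures.append(Exposure(m, edges[5], edges[6], _ANCHORS[m], 6))

    return exposures, truth


def simulate_trial(
    spec: ScenarioSpec,
    noise: NoiseModel | None = None,
    seed: int = 0,
    config: DetectionConfig | None = None,
) -> SimulatedTrial:
    """Render a scripted condition into an observation stream.

    Deterministic given (spec, noise, seed): all randomness (position
    jitter, dropout, occlusion, glimpses) flows from one generator seeded
    with ``seed``.
    """
    noise = noise or NoiseModel()
    config = config or DetectionConfig()
    rng = np.random.default_rng(seed)
    exposures, truth = build_script(spec)
    total = truth[6][1]
    period = config.frame_period
    p_drop = dropout_probability(noise, spec.actor_distance)

    # Fold occlusion: drop whole scripted regions for a phase.
    if noise.fold_occlusion_p > 0:
        occluded: set[tuple[int, int]] = set()  # (phase, marker)
        by_phase: dict[int, set[int]] = {}
        for e in exposures:
            by_phase.setdefault(e.phase, set()).add(e.marker_id)
        for ph in sorted(by_phase):
            for m in sorted(by_phase[ph]):
                if rng.random() < noise.fold_occlusion_p:
                    occluded.add((ph, m))
        exposures = [e for e in exposures if (e.phase, e.marker_id) not in occluded]

    # Glimpses: transient back/inside sightings during transition phases.
    if noise.glimpse_rate_hz > 0:
        wrong = (
            (_SHIRT_BACK, _SHIRT_INSIDE, 9)
            if spec.condition.garment is Garment.SHIRT
            else (_PANTS_BACK, _PANTS_INSIDE, 19)
        )
        for ph in (3, 5):
            a, b = truth[ph]
            # A detection can trail its last sighting by the gap tolerance,
            # so glimpse exposures stop short of the phase boundary to keep
            # any resulting event inside the transition phase.
            cutoff = b - config.gap_tolerance - config.frame_period
            t = a + rng.exponential(1.0 / noise.glimpse_rate_hz)
            while t < b:
                dur = rng.exponential(noise.glimpse_duration_s)
                m = int(rng.choice(wrong))
                end = min(t + dur, cutoff)
                if end > t:
                    exposures.append(Exposure(m, t, end, _ANCHORS[m], ph))
                t += rng.exponential(1.0 / noise.glimpse_rate_hz)

    # Render exposures on the global frame grid with bounded jitter.
    jitter: dict[int, tuple[float, float]] = {}
    obs: list[MarkerObservation] = []
    n_frames = int(np.floor(total / period)) + 1
    exposures.sort(key=lambda e: (e.t_start, e.marker_id))
    by_marker: dict[int, list[Exposure]] = {}
    for e in exposures:
        by_marker.setdefault(e.marker_id, []).append(e)

    for k in range(n_frames):
        t = k * period
        for m, exps in by_marker.items():
            active = None
            for e in exps:
                if e.t_start - 1e-9 <= t < e.t_end or (
                    e.t_end - e.t_start < period and e.t_start - 1e-9 <= t < e.t_start + period
                ):
                    active = e
                    break
            if active is None:
                continue
            if p_drop > 0 and rng.random() < p_drop:
                continue
            jx, jy = jitter.get(m, (0.0, 0.0))
            jx = float(np.clip(jx + rng.normal(0.0, 0.002), -0.01, 0.01))
            jy = float(np.clip(jy + rng.normal(0.0, 0.002), -0.01, 0.01))
            jitter[m] = (jx, jy)
            x = float(np.clip(active.anchor[0] + jx, 0.0, 1.0))
            y = float(np.clip(active.anchor[1] + jy, 0.0, 1.0))
            angle = float(rng.uniform(0.0, 360.0))
            obs.append(MarkerObservation(marker_id=m, x=x, y=y, angle=angle, t=round(t, 6)))

    obs.sort(key=lambda o: (o.t, o.marker_id))
    return SimulatedTrial(stream=obs, truth_phases=truth, truth_condition=spec.condition, seed=seed)


def simulate_study(
    roster: TrialRoster,
    noise: NoiseModel | None = None,
    seed: int = 0,
    config: DetectionConfig | None = None,
) -> list[tuple[TrialAssignment, SimulatedTrial]]:
    """One simulated trial per roster assignment.

    Per-trial seeds are ``seed + trial_index`` (stated splitting rule), so a
    study replays byte-identically from its master seed.
    """
    out = []
    for i, assignment in enumerate(enumerate_trials(roster, seed)):
        spec = ScenarioSpec(condition=assignment.condition)
        out.append(
            (assignment, simulate_trial(spec, noise=noise, seed=seed + i, config=config))
        )
    return out
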