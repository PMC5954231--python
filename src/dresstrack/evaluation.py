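"""Capability-study evaluation harness.

A trial is one person donning one garment under one of nine scripted
conditions (correct, back-to-front, inside-out, partial for both garments,
plus velcro-misaligned for the shirt).  Its detection sequence is segmented
into six narrative phases — (1) preliminary error/adjustment, (2) first limb
worn, (3) limb-to-limb transition, (4) second limb worn, (5) transition to
completion, (6) correct completion — and compared against the per-condition
expectation table.  Each required alternative-set with no matching event is a
*missed* detection; each event outside the phase's required and optional sets
is an *unexpected* detection.  Aggregation reproduces the study's summary
shape: per condition per phase, missed counts reported negative and
unexpected counts positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import DetectionEvent
from .model import DetectionLabel, Garment, PRECEDENCE_INDEX

L = DetectionLabel  # local shorthand for the expectation table


class ErrorMode(str, Enum):
    """The acted dressing error of a trial (or none, for correct)."""

    CORRECT = "correct"
    BACK_TO_FRONT = "back_to_front"
    INSIDE_OUT = "inside_out"
    PARTIAL = "partial"
    MISALIGNED = "misaligned"


@dataclass(frozen=True)
class Condition:
    """One of the nine study conditions (misaligned is shirt-only)."""

    garment: Garment
    error_mode: ErrorMode

    def __post_init__(self) -> None:
        if self.error_mode is ErrorMode.MISALIGNED and self.garment is not Garment.SHIRT:
            raise ValueError("the misaligned condition exists only for the shirt")

    @property
    def name(self) -> str:
        return f"{self.garment.value}:{self.error_mode.value}"

    @classmethod
    def parse(cls, text: str) -> "Condition":
        garment, _, mode = text.partition(":")
        return cls(Garment(garment), ErrorMode(mode))


SHIRT_CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(Garment.SHIRT, m)
    for m in (
        ErrorMode.CORRECT,
        ErrorMode.BACK_TO_FRONT,
        ErrorMode.INSIDE_OUT,
        ErrorMode.MISALIGNED,
        ErrorMode.PARTIAL,
    )
)
PANTS_CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(Garment.PANTS, m)
    for m in (
        ErrorMode.CORRECT,
        ErrorMode.BACK_TO_FRONT,
        ErrorMode.INSIDE_OUT,
        ErrorMode.PARTIAL,
    )
)
ALL_CONDITIONS: tuple[Condition, ...] = SHIRT_CONDITIONS + PANTS_CONDITIONS


@dataclass(frozen=True)
class PhaseExpectation:
    """Expected detections of one phase.

    ``required`` is a tuple of alternative-sets: each set is satisfied by any
    one of its labels (e.g. {R, L} — either limb first).  ``optional`` labels
    are acceptable but never required.
    """

    phase: int
    required: tuple[frozenset[DetectionLabel], ...] = ()
    optional: frozenset[DetectionLabel] = frozenset()

    def __post_init__(self) -> None:
        if not 1 <= self.phase <= 6:
            raise ValueError("phase must be in 1..6")
        for alt in self.required:
            if alt & self.optional:
                raise ValueError("required and optional label sets must be disjoint")

    @property
    def allowed(self) -> frozenset[DetectionLabel]:
        out = set(self.optional)
        for alt in self.required:
            out |= alt
        return frozenset(out)


def _exp(phase: int, required: Sequence[set] = (), optional: set | None = None) -> PhaseExpectation:
    return PhaseExpectation(
        phase=phase,
        required=tuple(frozenset(alt) for alt in required),
        optional=frozenset(optional or set()),
    )


_RL = {L.RIGHT, L.LEFT}

# Transcribed per-condition expectation rows.  Parenthesized entries of the
# study table are optional; bare letters are required; alternative first/second
# limb entries (R/L) are single alternative-sets.
_EXPECTATIONS: dict[tuple[Garment, ErrorMode], tuple[PhaseExpectation, ...]] = {
    (Garment.PANTS, ErrorMode.CORRECT): (
        _exp(1, optional={L.BACK}),
        _exp(2, required=[_RL]),
        _exp(3),
        _exp(4, required=[_RL]),
        _exp(5),
        _exp(6, required=[{L.COMPLETE}]),
    ),
    (Garment.PANTS, ErrorMode.BACK_TO_FRONT): (
        _exp(1, required=[{L.BACK}]),
        _exp(2, required=[_RL]),
        _exp(3),
        _exp(4, required=[_RL]),
        _exp(5),
        _exp(6, required=[{L.COMPLETE}]),
    ),
    (Garment.PANTS, ErrorMode.INSIDE_OUT): (
        _exp(1, required=[{L.INSIDE}], optional={L.BACK}),
        _exp(2, required=[_RL]),
        _exp(3),
        _exp(4, required=[_RL]),
        _exp(5),
        _exp(6, required=[{L.COMPLETE}]),
    ),
    (Garment.PANTS, ErrorMode.PARTIAL): (
        _exp(1, optional={L.BACK}),
        _exp(2, required=[_RL]),
        _exp(3),
        _exp(4, required=[_RL]),
        _exp(5),
        _exp(6, required=[{L.COMPLETE}]),
    ),
    (Garment.SHIRT, ErrorMode.CORRECT): (
        _exp(1, required=[{L.FRONT}], optional={L.BACK, L.INSIDE}),
        _exp(2, required=[_RL]),
        _exp(3, optional={L.PARTIAL, L.INSIDE, L.RIGHT, L.LEFT}),
        _exp(4, required=[_RL]),
        _exp(5, required=[{L.BOTH_ARMS}], optional={L.MISALIGNED, L.INSIDE, L.PARTIAL}),
        _exp(6, required=[{L.COMPLETE}]),
    ),
    (Garment.SHIRT, ErrorMode.BACK_TO_FRONT): (
        _exp(1, required=[{L.FRONT}, {L.BACK}], optional={L.INSIDE}),
        _exp(2, required=[_RL]),
        _exp(3, optional={L.PARTIAL, L.INSIDE, L.RIGHT, L.LEFT}),
        _exp(4, required=[_RL]),
        _exp(5, required=[{L.BOTH_ARMS}], optional={L.MISALIGNED, L.INSIDE, L.PARTIAL}),
        _exp(6, required=[{L.COMPLETE}]),
    ),
    (Garment.SHIRT, ErrorMode.INSIDE_OUT): (
        _exp(1, required=[{L.FRONT}, {L.INSIDE}], optional={L.BACK}),
        _exp(2, required=[_RL]),
        _exp(3, optional={L.PARTIAL, L.RIGHT, L.LEFT}),
        _exp(4, required=[_RL]),
        _exp(5, required=[{L.BOTH_ARMS}], optional={L.MISALIGNED, L.INSIDE}),
        _exp(6, required=[{L.COMPLETE}]),
    ),
    (Garment.SHIRT, ErrorMode.MISALIGNED): (
        _exp(1, required=[{L.FRONT}], optional={L.BACK, L.INSIDE}),
        _exp(2, required=[_RL]),
        _exp(3, optional={L.PARTIAL, L.INSIDE, L.RIGHT, L.LEFT}),
        _exp(4, required=[_RL]),
        # The acted misalignment makes M a required detection here.
        _exp(5, required=[{L.BOTH_ARMS}, {L.MISALIGNED}], optional={L.INSIDE}),
        _exp(6, required=[{L.COMPLETE}]),
    ),
    (Garment.SHIRT, ErrorMode.PARTIAL): (
        _exp(1, required=[{L.FRONT}], optional={L.BACK, L.INSIDE}),
        _exp(2, required=[_RL]),
        _exp(3, required=[{L.PARTIAL}], optional={L.INSIDE, L.RIGHT, L.LEFT}),
        _exp(4, required=[_RL]),
        _exp(5, required=[{L.BOTH_ARMS}], optional={L.MISALIGNED, L.INSIDE, L.PARTIAL}),
        _exp(6, required=[{L.COMPLETE}]),
    ),
}


def expected_for(condition: Condition) -> list[PhaseExpectation]:
    """The six :class:`PhaseExpectation` rows for one condition."""
    key = (condition.garment, condition.error_mode)
    if key not in _EXPECTATIONS:
        raise ValueError(f"no expectation table for {condition.name}")
    return list(_EXPECTATIONS[key])


def canonical_label(alternatives: Iterable[DetectionLabel]) -> str:
    """Canonical string for an alternative-set, e.g. {L, R} -> 'R/L'."""
    labs = sorted(set(alternatives), key=PRECEDENCE_INDEX.__getitem__)
    return "/".join(lab.value for lab in labs)


def segment_phases(
    events: Sequence[DetectionEvent], condition: Condition
) -> dict[int, list[DetectionEvent]]:
    """Milestone-based phase segmentation of a detection sequence.

    Phase 2 is the first R/L event; phase 4 the first subsequent event of the
    opposite side; phase 6 starts at the first C after that.  Everything else
    falls in the phases between.  Missing milestones leave later phases
    empty.  Deterministic for a fixed sequence.
    """
    phases: dict[int, list[DetectionEvent]] = {i: [] for i in range(1, 7)}
    first_side = None  # index of first R/L event
    second_side = None
    first_complete = None
    for i, e in enumerate(events):
        if first_side is None:
            if e.label in (L.RIGHT, L.LEFT):
                first_side = i
        elif second_side is None:
            opposite = L.LEFT if events[first_side].label is L.RIGHT else L.RIGHT
            if e.label is opposite:
                second_side = i
        elif first_complete is None:
            if e.label is L.COMPLETE:
                first_complete = i
    for i, e in enumerate(events):
        if first_side is None or i < first_side:
            phases[1].append(e)
        elif i == first_side:
            phases[2].append(e)
        elif second_side is None or i < second_side:
            phases[3].append(e)
        elif i == second_side:
            phases[4].append(e)
        elif first_complete is None or i < first_complete:
            phases[5].append(e)
        else:
            phases[6].append(e)
    return phases


@dataclass
class TrialScore:
    """Missed/unexpected detections of one trial, per phase."""

    condition: Condition
    missed: list[tuple[int, str]] = field(default_factory=list)
    unexpected: list[tuple[int, str]] = field(default_factory=list)
    repeats: list[tuple[int, str]] = field(default_factory=list)
    complete_detected: bool = False


def score_trial(events: Sequence[DetectionEvent], condition: Condition) -> TrialScore:
    """Score a detection sequence against its condition's expectation rows.

    Repeated identical labels within a phase satisfy a requirement once and
    are tallied in the separate ``repeats`` diagnostic, never as unexpected.
    """
    phases = segment_phases(events, condition)
    score = TrialScore(condition=condition)
    for exp in expected_for(condition):
        labels = [e.label for e in phases[exp.phase]]
        present = set(labels)
        for alt in exp.required:
            if not (present & alt):
                score.missed.append((exp.phase, canonical_label(alt)))
        allowed = exp.allowed
        seen_once: set[DetectionLabel] = set()
        for lab in labels:
            if lab in seen_once:
                score.repeats.append((exp.phase, lab.value))
            else:
                seen_once.add(lab)
                if lab not in allowed:
                    score.unexpected.append((exp.phase, lab.value))
    score.complete_detected = any(e.label is L.COMPLETE for e in phases[6])
    return score


def aggregate(
    scores: Sequence[TrialScore], exclude: Iterable[int] = ()
) -> pd.DataFrame:
    """Summary table: per condition per phase, missed (negative), unexpected
    (positive) and repeat counts plus per-condition totals.

    ``exclude`` lists indices of trials lost to recording failure; they are
    dropped before counting (their denominators shrink accordingly).
    """
    excluded = set(exclude)
    kept = [s for i, s in enumerate(scores) if i not in excluded]
    rows = []
    conditions = sorted({s.condition.name for s in kept})
    for cname in conditions:
        cscores = [s for s in kept if s.condition.name == cname]
        garment = cname.split(":", 1)[0]
        tot_m = tot_u = tot_r = 0
        for phase in range(1, 7):
            m = sum(1 for s in cscores for (p, _) in s.missed if p == phase)
            u = sum(1 for s in cscores for (p, _) in s.unexpected if p == phase)
            r = sum(1 for s in cscores for (p, _) in s.repeats if p == phase)
            tot_m += m
            tot_u += u
            tot_r += r
            rows.append(
                {
                    "garment": garment,
                    "condition": cname,
                    "phase": phase,
                    "missed": -m,
                    "unexpected": u,
                    "repeats": r,
                    "n_trials": len(cscores),
                }
            )
        rows.append(
            {
                "garment": garment,
                "condition": cname,
                "phase": "total",
                "missed": -tot_m,
                "unexpected": tot_u,
                "repeats": tot_r,
                "n_trials": len(cscores),
            }
        )
    return pd.DataFrame(
        rows, columns=["garment", "condition", "phase", "missed", "unexpected", "repeats", "n_trials"]
    )


@dataclass(frozen=True)
class TrialRoster:
    """Study design: every participant performs every condition a fixed
    number of times, in a per-participant randomized order (randomized block
    design)."""

    n_participants: int
    repetitions: int
    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.repetitions <= 0 or not self.conditions:
            raise ValueError("roster counts must be positive and conditions nonempty")

    @property
    def total_trials(self) -> int:
        return self.n_participants * self.repetitions * len(self.conditions)


def capability_study_roster() -> TrialRoster:
    """The laboratory study design: 11 participants x 9 conditions x 2 reps."""
    return TrialRoster(n_participants=11, repetitions=2, conditions=ALL_CONDITIONS)


@dataclass(frozen=True)
class TrialAssignment:
    participant: int
    condition: Condition
    repetition: int


def enumerate_trials(roster: TrialRoster, seed: int) -> list[TrialAssignment]:
    """Randomized-block trial order.

    Each participant's block (condition x repetition) is independently
    shuffled with a seed derived from ``seed`` and the participant index, so
    the restriction to any participant is a permutation of the full block.
    """
    out: list[TrialAssignment] = []
    for p in range(roster.n_participants):
        block = [
            (c, r) for c in roster.conditions for r in range(roster.repetitions)
        ]
        rng = np.random.default_rng([seed, p])
        order = rng.permutation(len(block))
        for idx in order:
            c, r = block[idx]
            out.append(TrialAssignment(participant=p, condition=c, repetition=r))
    return out
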