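"""JSON Lines readers/writers for observation streams and detections.

Event-stream files carry one observation per line with keys ``t``, ``id``,
``x``, ``y``, ``angle``; lines beginning with ``#`` are header comments and
are skipped.  The writer emits 6-decimal fixed-point for x/y so replayed
streams are byte-stable across platforms.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

from .model import Garment, MarkerObservation

if TYPE_CHECKING:  # pragma: no cover
    from .engine import DetectionEvent


def read_observations(path: str | Path) -> list[MarkerObservation]:
    out: list[MarkerObservation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rec = json.loads(line)
                out.append(
                    MarkerObservation(
                        marker_id=int(rec["id"]),
                        x=float(rec["x"]),
                        y=float(rec["y"]),
                        angle=float(rec.get("angle", 0.0)),
                        t=float(rec["t"]),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed observation line: {exc}")
    return out


def write_observations(path: str | Path, observations: Iterable[MarkerObservation]) -> None:
    with open(path, "w") as fh:
        for o in observations:
            fh.write(
                json.dumps(
                    {
                        "t": round(o.t, 6),
                        "id": o.marker_id,
                        "x": float(f"{o.x:.6f}"),
                        "y": float(f"{o.y:.6f}"),
                        "angle": round(o.angle, 3),
                    }
                )
                + "\n"
            )


def write_detections(path: str | Path, events: Sequence["DetectionEvent"]) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(
                json.dumps(
                    {
                        "t": round(e.t, 6),
                        "label": e.label.value,
                        "garment": e.garment.value,
                        "evidence": sorted(e.evidence),
                    }
                )
                + "\n"
            )


def read_detections(path: str | Path) -> list["DetectionEvent"]:
    from .engine import DetectionEvent
    from .model import DetectionLabel

    out: list[DetectionEvent] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rec = json.loads(line)
            out.append(
                DetectionEvent(
                    label=DetectionLabel(rec["label"]),
                    garment=Garment(rec["garment"]),
                    t=float(rec["t"]),
                    evidence=frozenset(int(i) for i in rec.get("evidence", [])),
                )
            )
    return out
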