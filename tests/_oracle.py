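"""Brute-force reference detector and random-stream generator for tests.

The oracle never keeps incremental visibility state: at every frame time it
rebuilds each marker's current run directly from the raw per-marker sighting
lists (binary search for the latest sighting, then a backward walk until the
first over-tolerance gap).  The rule layer and emission discipline
(edge-triggering, refractory, partial re-arm, label precedence) are
re-implemented here from the rule definitions, independently of the
incremental engine.
"""

from __future__ import annotations

import bisect

import numpy as np

from dresstrack.model import (
    DetectionConfig,
    DetectionLabel,
    Garment,
    MarkerObservation,
    Region,
    load_layout,
    validate_stream,
)

EPS = 1e-6
VELCRO = (208, 209, 211, 212)
PAIRS = ((208, 209), (211, 212))


def _runs(times, positions, t, gap):
    """(continuous_since, last_seen, last_pos) of the run active at t, or None."""
    i = bisect.bisect_right(times, t + EPS) - 1
    if i < 0:
        return None
    last = times[i]
    j = i
    while j > 0 and times[j] - times[j - 1] <= gap + EPS:
        j -= 1
    return times[j], last, positions[i]


def oracle_detect(stream, garment, config: DetectionConfig):
    """Full-rescan reference implementation of the detection rules."""
    stream = validate_stream(stream)
    layout = load_layout(garment)
    garment = layout.garment
    gap = config.gap_tolerance
    persist = config.persist_s
    timeout = config.partial_timeout_s

    times: dict[int, list[float]] = {}
    positions: dict[int, list[tuple[float, float]]] = {}
    frame_markers: dict[float, set[int]] = {}
    for o in stream:
        times.setdefault(o.marker_id, []).append(o.t)
        positions.setdefault(o.marker_id, []).append((o.x, o.y))
        frame_markers.setdefault(o.t, set()).add(o.marker_id)
    frame_ts = sorted(frame_markers)

    if garment is Garment.SHIRT:
        back = Region.SHIRT_BACK
        inside = (Region.SHIRT_INSIDE_CENTER, Region.SHIRT_INSIDE_SIDE)
        right_r, left_r = Region.SHIRT_FRONT_RIGHT, Region.SHIRT_FRONT_LEFT
        order = "FBIRLAMpC"
    else:
        back = Region.PANTS_BACK
        inside = (Region.PANTS_INSIDE_FRONT, Region.PANTS_INSIDE_BACK)
        right_r, left_r = Region.PANTS_LOW_RIGHT, Region.PANTS_LOW_LEFT
        order = "BIRLpC"

    def run_of(m, t):
        if m not in times:
            return None
        r = _runs(times[m], positions[m], t, gap)
        if r is None or t - r[1] > gap + EPS:
            return None
        return r

    def qualified(m, t):
        r = run_of(m, t)
        return r is not None and t - r[0] >= persist - EPS

    def qualified_set(region, t):
        return frozenset(m for m in layout.markers(region) if qualified(m, t))

    def status(code, t):
        """(satisfied, evidence, absent_side_region_for_p)"""
        if code == "F":
            ev = qualified_set(Region.SHIRT_FRONT, t)
            return bool(ev), ev, None
        if code == "B":
            ev = qualified_set(back, t)
            return bool(ev), ev, None
        if code == "I":
            ev = qualified_set(inside[0], t) | qualified_set(inside[1], t)
            return bool(ev), ev, None
        if code == "R":
            ev = qualified_set(right_r, t)
            return bool(ev), ev, None
        if code == "L":
            ev = qualified_set(left_r, t)
            return bool(ev), ev, None
        if code == "A":
            r, l = qualified_set(right_r, t), qualified_set(left_r, t)
            return (bool(r) and bool(l)), (r | l if r and l else frozenset()), None
        if code == "M":
            pos = {}
            for m in VELCRO:
                r = run_of(m, t)
                if r is not None:
                    pos[m] = r[2]
            if set(pos) < set(VELCRO):
                return False, frozenset(), None
            bad = any(
                abs(pos[a][1] - pos[b][1]) > config.y_align_max
                or abs(pos[a][0] - pos[b][0]) > config.x_align_max
                for a, b in PAIRS
            )
            return bad, (frozenset(VELCRO) if bad else frozenset()), None
        if code == "p":
            for vis, absent in ((right_r, left_r), (left_r, right_r)):
                vq = qualified_set(vis, t)
                if not vq:
                    continue
                longest = max(
                    (t - run_of(m, t)[0]) for m in vq
                )
                if longest < timeout - EPS:
                    continue
                seen = [times[m][bisect.bisect_right(times[m], t + EPS) - 1]
                        for m in layout.markers(absent)
                        if m in times and bisect.bisect_right(times[m], t + EPS) > 0]
                if not seen or t - max(seen) >= timeout - EPS:
                    return True, vq, absent
            return False, frozenset(), None
        if code == "C":
            if garment is Garment.PANTS:
                uppers = layout.markers(Region.PANTS_UPPER_FRONT)
                ok = all(qualified(m, t) for m in uppers)
                return ok, (uppers if ok else frozenset()), None
            if not all(qualified(m, t) for m in VELCRO):
                return False, frozenset(), None
            pos = {m: run_of(m, t)[2] for m in VELCRO}
            ok = all(
                abs(pos[a][1] - pos[b][1]) <= config.y_align_max
                and abs(pos[a][0] - pos[b][0]) <= config.x_align_max
                for a, b in PAIRS
            )
            return ok, (frozenset(VELCRO) if ok else frozenset()), None
        raise AssertionError(code)

    events = []
    prev = {c: False for c in order}
    last_emit = {}
    p_armed = True
    p_rearm = None
    for t in frame_ts:
        if p_rearm is not None and frame_markers[t] & layout.markers(p_rearm):
            p_armed = True
            p_rearm = None
        for code in order:
            sat, ev, absent = status(code, t)
            if sat and not prev[code]:
                ok = code not in last_emit or t - last_emit[code] >= config.refractory_s - EPS
                if ok and (code != "p" or p_armed):
                    events.append((t, code, ev))
                    last_emit[code] = t
                    if code == "p":
                        p_armed = False
                        p_rearm = absent
            prev[code] = sat
    return events


def random_stream(rng: np.random.Generator, garment: Garment,
                  n_frames: int = 1000, fps: float = 15.0) -> list[MarkerObservation]:
    """Random marker visibility stream with wandering positions.

    Visibility per marker follows a two-state Markov chain (runs of a few
    seconds, gaps likewise); positions random-walk across the whole frame so
    the velcro alignment rules are exercised on both sides of their
    thresholds.
    """
    layout = load_layout(garment)
    pool = sorted(layout.all_markers())
    k = int(rng.integers(4, 9))
    chosen = set(rng.choice(pool, size=min(k, len(pool)), replace=False).tolist())
    if garment is Garment.SHIRT and rng.random() < 0.5:
        chosen |= set(VELCRO)
    chosen = sorted(chosen)

    visible = {m: rng.random() < 0.3 for m in chosen}
    pos = {m: rng.uniform(0.1, 0.9, size=2) for m in chosen}
    out = []
    period = 1.0 / fps
    for kf in range(n_frames):
        t = round(kf * period, 6)
        for m in chosen:
            if visible[m]:
                visible[m] = rng.random() < 0.97
            else:
                visible[m] = rng.random() < 0.04
            if visible[m]:
                pos[m] = np.clip(pos[m] + rng.normal(0, 0.03, size=2), 0.0, 1.0)
                out.append(
                    MarkerObservation(
                        marker_id=int(m), x=float(pos[m][0]), y=float(pos[m][1]),
                        angle=float(rng.uniform(0, 360)), t=t,
                    )
                )
    return out
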