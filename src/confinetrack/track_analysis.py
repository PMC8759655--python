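"""Velocity, collision-episode detection, and collision-angle analysis.

Mirrors the manual measurements done on timelapse centroid tracks: mean
migration speed, detection of cell-cell contact episodes, the entering
(A-theta) and exiting (A-theta') angles of a collision relative to the
contacted cell's perimeter tangent, and the 120-s pre/post-contact speeds.

Angle conventions
-----------------
The reference line of a collision is the tangent to cell B's perimeter at
the contact point, i.e. the line perpendicular to the A->B centre line at
episode opening. The entering angle is the acute angle between A's incoming
direction and that tangent (0 = grazing, 90 = head-on). The exiting angle
is signed: positive when A leaves on the side it came from (reflection),
negative when it continues through to the far side; values below -90 mean
the tangential sense of motion also reversed (pushing through). Outgoing
directions that return to the incoming side steeper than the tangent are
folded back into [0, 90] so the angle stays measured from the tangent line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cell_sim import Track
from .geometry import Region

__all__ = [
    "CollisionEvent",
    "AngleHistogram",
    "mean_velocity",
    "detect_collisions",
    "collision_angles",
    "pre_post_velocity",
    "angle_histogram",
    "OUTCOME_REFLECT",
    "OUTCOME_PASS",
    "OUTCOME_PUSH",
    "OUTCOME_UNRESOLVED",
]

OUTCOME_REFLECT = "reflect"
OUTCOME_PASS = "pass"
OUTCOME_PUSH = "push"
OUTCOME_UNRESOLVED = "unresolved"

#: Direction-estimation window (s): displacement over this window before /
#: after the episode defines the incoming / outgoing direction. Single
#: frame-to-frame steps are noise-dominated at these speeds.
DEFAULT_DIRECTION_WINDOW_S = 30.0

#: Consecutive separated frames required to close an episode.
DEFAULT_HYSTERESIS_FRAMES = 2


@dataclass
class CollisionEvent:
    """One cell-cell contact episode, A being the approaching cell."""

    cell_a: int
    cell_b: int
    start_t: float  # s
    end_t: float  # s
    contact_point: tuple  # (x, y) um, midpoint of centres at opening
    entering_angle: Optional[float] = None  # deg, [0, 90]
    exiting_angle: Optional[float] = None  # deg, (-180, 90]
    outcome: str = OUTCOME_UNRESOLVED
    near_boundary: bool = False  # episode overlapped a boundary encounter

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass
class AngleHistogram:
    bin_edges: np.ndarray  # deg
    counts: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())


def mean_velocity(track: Track) -> float:
    """Mean centroid speed of a track in um/min.

    Average over frames of step displacement divided by the frame interval.
    """
    if len(track) < 2:
        raise ValueError("mean_velocity needs at least 2 frames")
    steps = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    dts = np.diff(track.t)
    if np.any(dts <= 0):
        raise ValueError("track times must be strictly increasing")
    return float(np.mean(steps / dts) * 60.0)


def _common_clock(tracks: Sequence[Track]) -> float:
    """Shared frame interval of a track set; error if clocks disagree."""
    intervals = set()
    for tr in tracks:
        if len(tr) > 1:
            intervals.update(np.round(np.diff(tr.t), 9))
    if len(intervals) > 1:
        raise ValueError(f"tracks do not share a frame clock: intervals {sorted(intervals)}")
    return intervals.pop() if intervals else 0.0


def detect_collisions(
    tracks: Sequence[Track],
    contact_distance: float,
    hysteresis_frames: int = DEFAULT_HYSTERESIS_FRAMES,
) -> list[CollisionEvent]:
    """Detect cell-cell contact episodes among a set of tracks.

    An episode opens at the first common frame where a pair's centre
    distance drops below ``contact_distance`` and closes at the first frame
    of a run of ``hysteresis_frames`` consecutive frames at or above it.
    One event is emitted per episode per unordered pair; ``end_t`` is the
    first frame of the closing run (an episode still open at the end of the
    overlap closes at the last common frame).
    """
    if contact_distance <= 0:
        raise ValueError("contact_distance must be positive")
    _common_clock(tracks)
    events: list[CollisionEvent] = []
    by_id = {tr.track_id: tr for tr in tracks}
    ids = sorted(by_id)
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a, b = by_id[ids[ai]], by_id[ids[bi]]
            # align on common frames
            common, ia, ib = np.intersect1d(a.frame, b.frame, return_indices=True)
            if len(common) == 0:
                continue
            d = np.linalg.norm(a.xy[ia] - b.xy[ib], axis=1)
            t = a.t[ia]
            xy_a, xy_b = a.xy[ia], b.xy[ib]
            open_i = None
            apart = 0
            for k in range(len(common)):
                if d[k] < contact_distance:
                    if open_i is None:
                        open_i = k
                    apart = 0
                elif open_i is not None:
                    apart += 1
                    if apart >= hysteresis_frames:
                        close_k = k - apart + 1
                        events.append(
                            _make_event(a, b, xy_a, xy_b, t, open_i, close_k)
                        )
                        open_i, apart = None, 0
            if open_i is not None:
                events.append(_make_event(a, b, xy_a, xy_b, t, open_i, len(common) - 1))
    events.sort(key=lambda e: (e.start_t, e.cell_a, e.cell_b))
    return events


def _make_event(a, b, xy_a, xy_b, t, open_i, close_i) -> CollisionEvent:
    pa, pb = xy_a[open_i], xy_b[open_i]
    # the approaching cell is "A": larger velocity component toward the other
    va = _opening_velocity(xy_a, open_i)
    vb = _opening_velocity(xy_b, open_i)
    sep = pb - pa
    nrm = np.linalg.norm(sep)
    u = sep / nrm if nrm > 0 else np.array([1.0, 0.0])
    if np.dot(va, u) >= np.dot(vb, -u):
        ca, cb = a.track_id, b.track_id
    else:
        ca, cb = b.track_id, a.track_id
    mid = (pa + pb) / 2.0
    return CollisionEvent(
        cell_a=ca,
        cell_b=cb,
        start_t=float(t[open_i]),
        end_t=float(t[close_i]),
        contact_point=(float(mid[0]), float(mid[1])),
    )


def _opening_velocity(xy: np.ndarray, i: int) -> np.ndarray:
    if i == 0:
        return np.zeros(2)
    return xy[i] - xy[i - 1]


def _window_displacement(track: Track, t0: float, t1: float) -> Optional[np.ndarray]:
    """Displacement of the track between times t0 and t1 (None if missing)."""
    i0 = np.flatnonzero(np.isclose(track.t, t0))
    i1 = np.flatnonzero(np.isclose(track.t, t1))
    if len(i0) == 0 or len(i1) == 0:
        return None
    return track.xy[i1[0]] - track.xy[i0[0]]


def collision_angles(
    event: CollisionEvent,
    tracks: Sequence[Track],
    direction_window: float = DEFAULT_DIRECTION_WINDOW_S,
    region: Optional[Region] = None,
    boundary_margin: Optional[float] = None,
) -> CollisionEvent:
    """Measure entering/exiting angles and classify the outcome of an event.

    The incoming direction is cell A's displacement over ``direction_window``
    seconds before episode opening; the outgoing direction its displacement
    over the same window after closing. If either window is unavailable the
    event is flagged ``unresolved`` and excluded from histograms. If a
    ``region`` is given, events whose contact point lies within
    ``boundary_margin`` of the pattern boundary are flagged ``near_boundary``
    (mixed cell + boundary events, excluded from histograms by default).

    Returns the same event, updated in place.
    """
    by_id = {tr.track_id: tr for tr in tracks}
    a, b = by_id[event.cell_a], by_id[event.cell_b]
    d_in = _window_displacement(a, event.start_t - direction_window, event.start_t)
    d_out = _window_displacement(a, event.end_t, event.end_t + direction_window)
    if region is not None and boundary_margin is not None:
        event.near_boundary = bool(
            region.signed_distance(np.asarray(event.contact_point)) < boundary_margin
        )
    if (
        d_in is None
        or d_out is None
        or np.linalg.norm(d_in) < 1e-12
        or np.linalg.norm(d_out) < 1e-12
    ):
        event.outcome = OUTCOME_UNRESOLVED
        return event

    # reference frame at opening: normal points from B's centre towards A
    ia = np.flatnonzero(np.isclose(a.t, event.start_t))[0]
    ib = np.flatnonzero(np.isclose(b.t, event.start_t))[0]
    sep = a.xy[ia] - b.xy[ib]
    nrm = np.linalg.norm(sep)
    nhat = sep / nrm if nrm > 0 else np.array([1.0, 0.0])

    u_in = d_in / np.linalg.norm(d_in)
    entering = math.degrees(math.asin(min(abs(float(np.dot(u_in, nhat))), 1.0)))

    # tangential reference direction: incoming tangential component
    t_comp = u_in - float(np.dot(u_in, nhat)) * nhat
    if np.linalg.norm(t_comp) < 1e-9:
        t_comp = np.array([-nhat[1], nhat[0]])  # head-on: either tangent sense
    t0 = t_comp / np.linalg.norm(t_comp)

    u_out = d_out / np.linalg.norm(d_out)
    alpha = math.degrees(
        math.atan2(float(np.dot(u_out, nhat)), float(np.dot(u_out, t0)))
    )
    exiting = 180.0 - alpha if alpha > 90.0 else alpha

    event.entering_angle = entering
    event.exiting_angle = exiting
    if exiting >= 0.0:
        event.outcome = OUTCOME_REFLECT
    elif exiting >= -90.0:
        event.outcome = OUTCOME_PASS
    else:
        event.outcome = OUTCOME_PUSH
    return event


def pre_post_velocity(
    event: CollisionEvent,
    tracks: Sequence[Track],
    window: float = 120.0,
) -> Optional[tuple[float, float]]:
    """Mean speed (um/min) of cell A in the ``window`` seconds before episode
    start and after episode end; None if either window is truncated."""
    by_id = {tr.track_id: tr for tr in tracks}
    a = by_id[event.cell_a]
    pre_mask = (a.t >= event.start_t - window - 1e-9) & (a.t <= event.start_t + 1e-9)
    post_mask = (a.t >= event.end_t - 1e-9) & (a.t <= event.end_t + window + 1e-9)
    expected = int(round(window / _common_clock([a]))) + 1 if len(a) > 1 else 0
    if pre_mask.sum() < expected or post_mask.sum() < expected:
        return None
    sub_pre = Track(a.track_id, a.frame[pre_mask], a.t[pre_mask], a.x[pre_mask], a.y[pre_mask])
    sub_post = Track(a.track_id, a.frame[post_mask], a.t[post_mask], a.x[post_mask], a.y[post_mask])
    return mean_velocity(sub_pre), mean_velocity(sub_post)


def angle_histogram(
    events: Iterable[CollisionEvent],
    which: str = "exiting",
    bin_width: float = 30.0,
    include_near_boundary: bool = False,
) -> AngleHistogram:
    """Histogram of collision angles over resolved events.

    Entering angles are binned over [0, 90]; exiting over [-180, 90].
    Unresolved events, and by default events that overlapped a boundary
    encounter, are excluded.
    """
    vals = [
        (e.entering_angle if which == "entering" else e.exiting_angle)
        for e in events
        if e.outcome != OUTCOME_UNRESOLVED
        and (include_near_boundary or not e.near_boundary)
    ]
    lo, hi = (0.0, 90.0) if which == "entering" else (-180.0, 90.0)
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    counts, _ = np.histogram(np.clip(vals, lo, hi - 1e-9), bins=edges)
    return AngleHistogram(bin_edges=edges, counts=counts)
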