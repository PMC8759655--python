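"""Cell-boundary encounter detection and angle analysis.

When a migrating cell reaches the edge of the adhesive pattern it cannot
adhere beyond it: it either turns and follows the boundary or migrates away.
This module detects those encounters from centroid tracks, measures the
entering/exiting angles against the local boundary tangent, classifies the
boundary's curvature (linear / concave arc / convex arc), and decides
whether the cell followed the boundary after contact.

Both angles are unsigned in [0, 90] (0 = parallel to the boundary,
90 = perpendicular): the cell cannot exit the region, so there is no
near/far side distinction as in cell-cell collisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cell_sim import Track
from .geometry import BoundaryClass, CornerPointError, Region
from .track_analysis import DEFAULT_DIRECTION_WINDOW_S, _window_displacement

__all__ = [
    "BoundaryEncounter",
    "detect_boundary_encounters",
    "encounter_angles",
    "classify_following",
]

#: Extra distance (um) a cell must retreat beyond near_distance to close an
#: encounter, suppressing chatter at the detection threshold.
DEFAULT_HYSTERESIS_UM = 1.0


@dataclass
class BoundaryEncounter:
    track_id: int
    start_t: float  # s
    end_t: float  # s
    boundary_class: Optional[BoundaryClass]  # None when opened at a corner
    contact_point: tuple  # nearest boundary point at opening, um
    entering_angle: Optional[float] = None  # deg [0, 90]
    exiting_angle: Optional[float] = None  # deg [0, 90]
    followed_boundary: Optional[bool] = None
    resolved: bool = True  # False when direction windows were unavailable

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


def detect_boundary_encounters(
    track: Track,
    region: Region,
    near_distance: float,
    hysteresis: float = DEFAULT_HYSTERESIS_UM,
) -> list[BoundaryEncounter]:
    """Detect boundary-contact episodes of one track.

    An encounter opens when the signed distance to the boundary drops below
    ``near_distance`` and closes when it exceeds ``near_distance +
    hysteresis`` (an encounter still open at the last frame closes there).
    The curvature class is taken at the nearest boundary point of the
    opening frame; corner openings get class None.
    """
    if near_distance <= 0:
        raise ValueError("near_distance must be positive")
    sd = region.signed_distance_many(track.xy)
    encounters: list[BoundaryEncounter] = []
    open_i: Optional[int] = None
    for k in range(len(track)):
        if open_i is None:
            if sd[k] < near_distance:
                open_i = k
        elif sd[k] > near_distance + hysteresis:
            encounters.append(_make_encounter(track, region, open_i, k - 1))
            open_i = None
    if open_i is not None:
        encounters.append(_make_encounter(track, region, open_i, len(track) - 1))
    return encounters


def _make_encounter(track, region, open_i, close_i) -> BoundaryEncounter:
    bp = region.nearest_boundary_point(track.xy[open_i])
    try:
        _, cls = region.boundary_tangent_and_class(bp, tol=1e-6)
    except CornerPointError:
        cls = None
    return BoundaryEncounter(
        track_id=track.track_id,
        start_t=float(track.t[open_i]),
        end_t=float(track.t[close_i]),
        boundary_class=cls,
        contact_point=(float(bp[0]), float(bp[1])),
    )


def _angle_to_tangent(direction: np.ndarray, region: Region, point: np.ndarray) -> float:
    """Acute angle (deg) between a direction and the boundary tangent at the
    boundary point nearest ``point``."""
    bp = region.nearest_boundary_point(point)
    tangent, _ = region.boundary_tangent_and_class(bp, tol=np.inf)
    u = direction / np.linalg.norm(direction)
    c = abs(float(tangent[0] * u[1] - tangent[1] * u[0]))  # |sin| vs tangent
    return math.degrees(math.asin(min(c, 1.0)))


def encounter_angles(
    enc: BoundaryEncounter,
    track: Track,
    region: Region,
    direction_window: float = DEFAULT_DIRECTION_WINDOW_S,
) -> BoundaryEncounter:
    """Measure entering and exiting angles of an encounter (updated in place).

    The incoming direction is the displacement over ``direction_window``
    seconds before opening, measured against the tangent at the opening
    contact point; the outgoing direction likewise after closing, against
    the tangent at the closing frame's nearest boundary point. Encounters
    with missing windows are flagged unresolved and excluded from summaries.
    """
    d_in = _window_displacement(track, enc.start_t - direction_window, enc.start_t)
    d_out = _window_displacement(track, enc.end_t, enc.end_t + direction_window)
    if (
        d_in is None
        or d_out is None
        or np.linalg.norm(d_in) < 1e-12
        or np.linalg.norm(d_out) < 1e-12
    ):
        enc.resolved = False
        return enc
    try:
        enc.entering_angle = _angle_to_tangent(
            d_in, region, np.asarray(enc.contact_point)
        )
        i_close = int(np.flatnonzero(np.isclose(track.t, enc.end_t))[0])
        enc.exiting_angle = _angle_to_tangent(d_out, region, track.xy[i_close])
    except CornerPointError:
        enc.resolved = False
    return enc


def classify_following(
    enc: BoundaryEncounter,
    track: Track,
    region: Region,
    near_distance: float,
    follow_window: float = 120.0,
    parallel_tolerance: float = 30.0,
    settle_time: float = 30.0,
) -> bool:
    """True iff the cell followed the boundary after contact.

    Following means that for ``follow_window`` seconds after opening the
    cell (a) stays within ``near_distance`` of the boundary throughout and
    (b) moves within ``parallel_tolerance`` degrees of the local tangent at
    every step after an initial ``settle_time`` of reorientation (cells
    first retract protrusions and turn before travelling along the edge).
    Returns False when the window runs past the end of the track.
    """
    t0, t1 = enc.start_t, enc.start_t + follow_window
    mask = (track.t >= t0 - 1e-9) & (track.t <= t1 + 1e-9)
    idx = np.flatnonzero(mask)
    if len(idx) < 2 or track.t[idx[-1]] < t1 - 1e-9:
        enc.followed_boundary = False
        return False
    pts = track.xy[idx]
    sd = region.signed_distance_many(pts)
    if np.any(sd >= near_distance + DEFAULT_HYSTERESIS_UM):
        enc.followed_boundary = False
        return False
    times = track.t[idx]
    steps = np.diff(pts, axis=0)
    for tstep, p, s in zip(times[:-1], pts[:-1], steps):
        if tstep < t0 + settle_time - 1e-9:
            continue  # reorientation phase
        n = np.linalg.norm(s)
        if n < 1e-12:
            continue  # stationary step carries no direction
        try:
            ang = _angle_to_tangent(s, region, p)
        except CornerPointError:
            enc.followed_boundary = False
            return False
        if ang > parallel_tolerance:
            enc.followed_boundary = False
            return False
    enc.followed_boundary = True
    return True
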