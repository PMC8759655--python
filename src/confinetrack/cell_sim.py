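"""Agent-based synthetic trajectory generator.

Emulates timelapse centroid tracks of fast-migrating amoeboid cells confined
to an adhesive micropattern: persistent random-walk motility, boundary
following / reflection at the pattern edge, cell-cell collision outcomes
(reflect / pass / push), and stochastic division with Gaussian lifetimes.

The module also provides :func:`simulate_rigid_particles`, a positional
Monte-Carlo of hard disks in the circular arena that serves as an
independent cross-check of the analytic collision-rate model, and
:func:`sample_lineage`, the temporal marginal of the division process (used
when only division statistics are needed).

All randomness flows from a single integer seed; identical configurations
produce identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .collision_model import CollisionModelParams, DEFAULT_PARAMS
from .geometry import (
    CornerPointError,
    Disk,
    Rectangle,
    Region,
    region_from_dict,
    region_to_dict,
)

__all__ = [
    "SimConfig",
    "DivisionConfig",
    "Track",
    "LineageNode",
    "LineageTree",
    "SimResult",
    "simulate",
    "sample_lineage",
    "simulate_rigid_particles",
    "generate_fixture",
    "FIXTURE_PRESETS",
    "OverPackedError",
]


class OverPackedError(RuntimeError):
    """Raised when initial non-overlapping placement cannot be found."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class Track:
    """One cell's time-ordered centroid positions."""

    track_id: int
    frame: np.ndarray  # int, strictly increasing
    t: np.ndarray  # seconds
    x: np.ndarray  # um
    y: np.ndarray  # um
    radius: Optional[float] = None  # um

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frame) == len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("track columns must have equal length")
        if len(self.frame) > 1 and np.any(np.diff(self.frame) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class LineageNode:
    track_id: int
    parent_id: Optional[int]
    birth_s: float
    rounding_s: Optional[float] = None
    abscission_s: Optional[float] = None
    child_ids: tuple = ()

    @property
    def divided(self) -> bool:
        return self.abscission_s is not None


class LineageTree:
    """Parent/child relations with rounding and abscission times.

    Divisions are binary: a dividing track ends at abscission and is replaced
    by exactly two child tracks born at that instant.
    """

    def __init__(self) -> None:
        self.nodes: dict[int, LineageNode] = {}

    def add_founder(self, track_id: int, birth_s: float = 0.0) -> LineageNode:
        node = LineageNode(track_id, None, birth_s)
        self.nodes[track_id] = node
        return node

    def record_division(
        self,
        parent_id: int,
        child_ids: tuple[int, int],
        rounding_s: float,
        abscission_s: float,
    ) -> None:
        if rounding_s >= abscission_s:
            raise ValueError("rounding must precede abscission")
        parent = self.nodes[parent_id]
        parent.rounding_s = rounding_s
        parent.abscission_s = abscission_s
        parent.child_ids = tuple(child_ids)
        for cid in child_ids:
            self.nodes[cid] = LineageNode(cid, parent_id, abscission_s)

    def founders(self) -> list[LineageNode]:
        return [n for n in self.nodes.values() if n.parent_id is None]

    def validate(self) -> None:
        for n in self.nodes.values():
            if n.divided:
                if len(n.child_ids) != 2:
                    raise ValueError(f"track {n.track_id}: divisions must be binary")
                if not (n.rounding_s < n.abscission_s):
                    raise ValueError(f"track {n.track_id}: rounding_s >= abscission_s")
                for cid in n.child_ids:
                    if not math.isclose(self.nodes[cid].birth_s, n.abscission_s):
                        raise ValueError(
                            f"track {cid}: birth must equal parent abscission"
                        )

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_outcome_table() -> dict:
    # Illustrative, not fitted: shallow contacts mostly reflect, intermediate
    # mostly pass through, steep contacts push or pass.
    return {
        (0.0, 30.0): {"reflect": 0.6, "pass": 0.3, "push": 0.1},
        (30.0, 60.0): {"reflect": 0.2, "pass": 0.6, "push": 0.2},
        (60.0, 90.0): {"reflect": 0.1, "pass": 0.45, "push": 0.45},
    }


@dataclass
class DivisionConfig:
    enabled: bool = False
    doubling_mean_h: float = 9.3
    doubling_sd_h: float = 1.6
    min_lifetime_h: float = 0.5
    rounding_duration_min: float = 5.0

    def __post_init__(self) -> None:
        if self.enabled:
            if self.doubling_mean_h <= 0 or self.doubling_sd_h < 0:
                raise ValueError("doubling time parameters must be positive")
            if self.min_lifetime_h * 60.0 <= self.rounding_duration_min:
                raise ValueError("min lifetime must exceed the rounding duration")


@dataclass
class SimConfig:
    """Study conditions for the synthetic timelapse.

    Defaults emulate the experimental scenario: a 100-um-diameter circular
    adhesive island imaged at 10-s intervals, cells migrating at
    3.9 +/- 0.6 um/min, dividing with Gaussian doubling times of
    9.3 +/- 1.6 h.
    """

    region: Region = field(default_factory=lambda: Disk((0.0, 0.0), 50.0))
    n_cells: int = 5
    cell_radius: float = 2.0  # um; footprint ~12.6 um^2 (200 cells <-> 32%)
    speed_mean: float = 3.9  # um/min
    speed_sd: float = 0.6  # um/min
    persistence_time: float = 60.0  # s; heading decorrelation time
    frame_interval: float = 10.0  # s
    duration: float = 3600.0  # s
    boundary_follow_angle: float = 30.0  # deg; shallower approaches follow
    boundary_sense_distance: Optional[float] = None  # um; default cell_radius
    boundary_guidance_factor: float = 0.4  # turning-noise scale while following
    collisions_enabled: bool = True
    collision_outcome_table: dict = field(default_factory=_default_outcome_table)
    division: DivisionConfig = field(default_factory=DivisionConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cell_radius, self.speed_mean, self.persistence_time,
               self.frame_interval, self.duration) <= 0:
            raise ValueError("lengths and durations must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        n_steps = self.duration / self.frame_interval
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("frame_interval must divide duration")
        for bin_, probs in self.collision_outcome_table.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"outcome probabilities for bin {bin_} must sum to 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region"] = region_to_dict(self.region)
        d["collision_outcome_table"] = {
            f"{lo:g}-{hi:g}": probs
            for (lo, hi), probs in self.collision_outcome_table.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "region" in d:
            d["region"] = region_from_dict(d["region"])
        if "collision_outcome_table" in d:
            table = {}
            for key, probs in d["collision_outcome_table"].items():
                lo, hi = (float(v) for v in key.split("-"))
                table[(lo, hi)] = dict(probs)
            d["collision_outcome_table"] = table
        if "division" in d and isinstance(d["division"], dict):
            d["division"] = DivisionConfig(**d["division"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SimResult:
    tracks: list
    lineage: LineageTree
    config: SimConfig
    n_collision_episodes: int = 0


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, minimum, size=None):
    """Normal(mean, sd) conditioned on >= minimum, by rejection."""
    if sd == 0:
        out = np.full(size if size is not None else (), mean, dtype=float)
        return out if size is not None else float(out)
    n = 1 if size is None else int(np.prod(size))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 8))
        ok = draw[draw >= minimum]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out.reshape(size) if size is not None else float(out[0])


def _place_without_overlap(
    region: Region, n: int, min_separation: float, rng, margin: float = 0.0
) -> np.ndarray:
    """Random sequential placement with pairwise separation >= min_separation.

    ``margin`` keeps centres at least that far inside the boundary.
    """
    placed = np.empty((n, 2))
    count = 0
    attempts = 0
    max_attempts = 20_000 * max(n, 1)
    while count < n:
        if attempts > max_attempts:
            raise OverPackedError(
                f"could not place {n} cells with separation {min_separation} um"
            )
        attempts += 1
        p = region.sample_points(1, rng)[0]
        if margin > 0 and region.signed_distance(p) < margin:
            continue
        if count and np.any(np.linalg.norm(placed[:count] - p, axis=1) < min_separation):
            continue
        placed[count] = p
        count += 1
    return placed


def _unit(theta):
    return np.column_stack([np.cos(theta), np.sin(theta)])


def _entering_angle_deg(u: np.ndarray, normal: np.ndarray) -> float:
    """Acute angle (deg) between direction ``u`` and the line orthogonal to
    ``normal`` -- i.e. how steeply ``u`` approaches a boundary whose unit
    normal is ``normal``. 0 = parallel to the boundary, 90 = head-on."""
    c = abs(float(np.dot(u, normal)))
    return math.degrees(math.asin(min(c, 1.0)))


# ---------------------------------------------------------------------------
# Agent-based simulation
# ---------------------------------------------------------------------------


def simulate(config: SimConfig) -> SimResult:
    """Run the agent-based simulation and return tracks plus lineage.

    Motility: each cell carries a constant speed drawn from a truncated
    normal and a heading that diffuses with variance 2*dt/persistence_time
    per step. Boundary interaction: within ``boundary_sense_distance`` of
    the pattern edge, a cell whose heading lies within
    ``boundary_follow_angle`` of the local tangent enters the *following*
    state -- its motion is constrained along the tangent (the retracting
    pseudopods cannot gain ground beyond the edge) with turning noise
    reduced by ``boundary_guidance_factor``, and it keeps crawling along
    the boundary until a decisive inward turn (beyond the follow angle)
    releases it. Steeper outward headings are specularly reflected. New
    cell-cell contacts sample an outcome (reflect / pass / push) from the
    configured per-entering-angle table. With division enabled, each cell
    divides after a truncated-Gaussian lifetime, pausing in a rounded
    (stationary) state for rounding_duration before abscission.
    """
    rng = np.random.default_rng(config.seed)
    region = config.region
    dt = config.frame_interval
    n_steps = config.n_frames - 1
    follow_thresh = config.boundary_follow_angle
    two_r = 2.0 * config.cell_radius
    div = config.division
    rounding_s = div.rounding_duration_min * 60.0

    # --- state ---
    pos = _place_without_overlap(
        region, config.n_cells, two_r, rng, margin=min(config.cell_radius, 1.0)
    )
    n = config.n_cells
    ids = np.arange(n)
    next_id = n
    heading = rng.uniform(0.0, 2.0 * math.pi, size=n)
    speed = _truncated_normal(rng, config.speed_mean, config.speed_sd, 0.0, size=n) / 60.0
    birth_t = np.zeros(n)
    lifetime = np.full(n, np.inf)
    if div.enabled:
        lifetime = (
            _truncated_normal(
                rng, div.doubling_mean_h, div.doubling_sd_h, div.min_lifetime_h, size=n
            )
            * 3600.0
        )

    lineage = LineageTree()
    for i in ids:
        lineage.add_founder(int(i))

    history: dict[int, list] = {int(i): [(0, 0.0, pos[k, 0], pos[k, 1])] for k, i in enumerate(ids)}
    active_contacts: dict[tuple[int, int], str] = {}
    n_episodes = 0

    sin_follow = math.sin(math.radians(follow_thresh))
    sense = (
        config.boundary_sense_distance
        if config.boundary_sense_distance is not None
        else config.cell_radius
    )
    following = np.zeros(n, dtype=bool)
    noise_sd = math.sqrt(2.0 * dt / config.persistence_time)

    for step in range(1, n_steps + 1):
        t = step * dt

        # heading diffusion, damped by contact guidance while following
        # (rounded cells stay put regardless)
        age = t - birth_t
        rounded = div.enabled & (age >= lifetime - rounding_s)
        noise_scale = np.where(following, config.boundary_guidance_factor, 1.0)
        heading = heading + noise_scale * rng.normal(0.0, noise_sd, size=len(heading))
        u = _unit(heading)
        step_len = np.where(rounded, 0.0, speed * dt)
        proposed = pos + u * step_len[:, None]

        # --- boundary rule ---
        near = (region.signed_distance_many(pos) < sense) | (
            region.signed_distance_many(proposed) < 0.0
        )
        for k in np.flatnonzero(near):
            if step_len[k] == 0.0:
                continue
            bp = region.nearest_boundary_point(pos[k])
            inward = pos[k] - bp  # points into the region for interior points
            norm = np.linalg.norm(inward)
            if norm < 1e-12:
                try:
                    inward = region.inward_normal(bp)
                except CornerPointError:
                    # exactly at a corner: aim at the region's centre
                    xmin, ymin, xmax, ymax = region.bounds()
                    c = np.array([(xmin + xmax) / 2.0, (ymin + ymax) / 2.0])
                    delta = c - bp
                    inward = delta / max(np.linalg.norm(delta), 1e-12)
            else:
                inward = inward / norm
            uk = u[k]
            normal_comp = float(np.dot(uk, inward))  # <0 when heading outward
            angle_sin = min(abs(normal_comp), 1.0)
            if angle_sin <= sin_follow or (following[k] and normal_comp < 0.0):
                # capture into / continue boundary following: headings in the
                # follow cone are captured; a cell already crawling that noses
                # outward cannot gain ground beyond the edge and keeps
                # crawling (only a decisive inward turn releases it below).
                # Hug the edge and crawl along the boundary curve.
                tangent = np.array([-inward[1], inward[0]])
                sgn = 1.0 if float(np.dot(uk, tangent)) >= 0.0 else -1.0
                new_u = sgn * tangent
                following[k] = True
                heading[k] = math.atan2(new_u[1], new_u[0])
                proposed[k] = region.nearest_boundary_point(
                    pos[k] + new_u * step_len[k]
                )
                continue
            if normal_comp < 0.0:
                # steep outward heading: specular reflection off the edge
                new_u = uk - 2.0 * normal_comp * inward
                following[k] = False
            else:
                # decisive inward turn: release from the boundary
                following[k] = False
                continue
            heading[k] = math.atan2(new_u[1], new_u[0])
            proposed[k] = pos[k] + new_u * step_len[k]
        following &= near  # cells away from the boundary are free
        # clamp anything still outside (curvature overshoot) onto the boundary
        sd = region.signed_distance_many(proposed)
        bad = np.flatnonzero(sd < 0.0)
        if len(bad):
            proposed[bad] = region.nearest_boundary_many(proposed[bad])
        pos = proposed

        # --- cell-cell collisions ---
        if config.collisions_enabled and len(pos) > 1:
            dmat = squareform(pdist(pos))
            iu, ju = np.triu_indices(len(pos), k=1)
            contact = dmat[iu, ju] < two_r
            current = {
                (int(ids[i]), int(ids[j]))
                for i, j in zip(iu[contact], ju[contact])
            }
            # close episodes that separated
            for pair in [p for p in active_contacts if p not in current]:
                del active_contacts[pair]
            # open new episodes
            idx_of = {int(cid): k for k, cid in enumerate(ids)}
            for pair in sorted(current - set(active_contacts)):
                a_id, b_id = pair
                ia, ib = idx_of[a_id], idx_of[b_id]
                sep = pos[ia] - pos[ib]
                d = np.linalg.norm(sep)
                if d < 1e-12:
                    continue
                nhat = sep / d  # from B towards A
                ua, ub = _unit(heading[[ia, ib]])
                # "A" is the cell approaching faster along the centre line
                if -np.dot(ua, nhat) >= np.dot(ub, nhat):
                    mover, target, n_to_mover = ia, ib, nhat
                else:
                    mover, target, n_to_mover = ib, ia, -nhat
                um = _unit(heading[[mover]])[0]
                theta = _entering_angle_deg(um, n_to_mover)
                outcome = _sample_outcome(
                    config.collision_outcome_table, theta, rng
                )
                active_contacts[pair] = outcome
                n_episodes += 1
                # boundary-following cells hold their course through
                # contacts: edge guidance dominates transient cell-cell
                # adhesion (episodes are still recorded above)
                if following[mover] or following[target]:
                    continue
                if outcome == "reflect":
                    new_u = um - 2.0 * float(np.dot(um, n_to_mover)) * n_to_mover
                    heading[mover] = math.atan2(new_u[1], new_u[0])
                elif outcome == "push":
                    # displace the target along the contact normal
                    new_bp = pos[mover] - n_to_mover * two_r
                    if region.signed_distance(new_bp) >= 0.0:
                        pos[target] = new_bp
                    else:
                        pos[target] = region.nearest_boundary_point(new_bp)
                # "pass": headings unchanged, overlap tolerated for the episode

        # --- record ---
        for k, cid in enumerate(ids):
            history[int(cid)].append((step, t, pos[k, 0], pos[k, 1]))

        # --- divisions ---
        if div.enabled:
            age = t - birth_t
            dividing = np.flatnonzero(age >= lifetime)
            if len(dividing):
                keep = np.setdiff1d(np.arange(len(ids)), dividing)
                new_pos, new_head, new_speed = [], [], []
                new_birth, new_life, new_ids = [], [], []
                for k in dividing:
                    parent = int(ids[k])
                    axis = rng.uniform(0.0, 2.0 * math.pi)
                    offset = np.array([math.cos(axis), math.sin(axis)])
                    children = (next_id, next_id + 1)
                    next_id += 2
                    round_t = max(t - rounding_s, birth_t[k])
                    lineage.record_division(parent, children, round_t, t)
                    for sgn, cid in zip((1.0, -1.0), children):
                        cp = pos[k] + sgn * offset * config.cell_radius
                        if region.signed_distance(cp) < 0.0:
                            cp = region.nearest_boundary_point(cp)
                        new_pos.append(cp)
                        new_head.append(axis if sgn > 0 else axis + math.pi)
                        new_speed.append(
                            _truncated_normal(
                                rng, config.speed_mean, config.speed_sd, 0.0
                            )
                            / 60.0
                        )
                        new_birth.append(t)
                        new_life.append(
                            _truncated_normal(
                                rng,
                                div.doubling_mean_h,
                                div.doubling_sd_h,
                                div.min_lifetime_h,
                            )
                            * 3600.0
                        )
                        new_ids.append(cid)
                        history[cid] = [(step, t, cp[0], cp[1])]
                pos = np.vstack([pos[keep], np.array(new_pos)])
                following = np.concatenate(
                    [following[keep], np.zeros(len(new_ids), dtype=bool)]
                )
                heading = np.concatenate([heading[keep], new_head])
                speed = np.concatenate([speed[keep], new_speed])
                birth_t = np.concatenate([birth_t[keep], new_birth])
                lifetime = np.concatenate([lifetime[keep], new_life])
                ids = np.concatenate([ids[keep], np.array(new_ids, dtype=int)])
                active_contacts = {
                    p: o
                    for p, o in active_contacts.items()
                    if p[0] in ids and p[1] in ids
                }

    tracks = []
    for cid, rows in sorted(history.items()):
        arr = np.array(rows)
        tracks.append(
            Track(
                track_id=cid,
                frame=arr[:, 0].astype(int),
                t=arr[:, 1],
                x=arr[:, 2],
                y=arr[:, 3],
                radius=config.cell_radius,
            )
        )
    lineage.validate()
    return SimResult(tracks, lineage, config, n_episodes)


def _sample_outcome(table: dict, entering_angle: float, rng) -> str:
    for (lo, hi), probs in table.items():
        if lo <= entering_angle <= hi if hi >= 90.0 else lo <= entering_angle < hi:
            names = sorted(probs)
            p = np.array([probs[k] for k in names])
            return names[rng.choice(len(names), p=p / p.sum())]
    raise ValueError(f"no outcome bin covers entering angle {entering_angle:.1f} deg")


# ---------------------------------------------------------------------------
# Lineage-only sampling (temporal marginal of the division process)
# ---------------------------------------------------------------------------


def sample_lineage(
    division: DivisionConfig,
    n_founders: int,
    duration_h: float,
    seed: int | np.random.Generator = 0,
) -> LineageTree:
    """Sample a lineage tree without spatial dynamics.

    Division lifetimes are independent of cell position in the full
    simulation, so this is exactly the distribution of lineages that
    :func:`simulate` produces, at negligible cost. Useful when only division
    timing statistics are needed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration_s = duration_h * 3600.0
    rounding_s = division.rounding_duration_min * 60.0
    lineage = LineageTree()
    next_id = n_founders
    # breadth-first over birth events keeps ids in birth order
    queue: list[tuple[float, int]] = []
    for i in range(n_founders):
        lineage.add_founder(i)
        queue.append((0.0, i))
    qi = 0
    while qi < len(queue):
        birth, cid = queue[qi]
        qi += 1
        life = (
            _truncated_normal(
                rng, division.doubling_mean_h, division.doubling_sd_h,
                division.min_lifetime_h,
            )
            * 3600.0
        )
        absc = birth + life
        if absc > duration_s:
            continue  # alive at the end of observation
        children = (next_id, next_id + 1)
        next_id += 2
        lineage.record_division(cid, children, max(absc - rounding_s, birth), absc)
        queue.extend((absc, c) for c in children)
    lineage.validate()
    return lineage


# ---------------------------------------------------------------------------
# Rigid-particle Monte-Carlo oracle
# ---------------------------------------------------------------------------

#: Heading persistence (s) of the rigid-particle oracle; equal to the time
#: step, i.e. headings are memoryless (redrawn every step).
RIGID_HEADING_PERSISTENCE_S = 5.0

#: Oracle time step (s); V*dt ~ L/26, safely below the tunnelling limit.
RIGID_DT_S = 5.0

#: Consecutive separated frames required to close a contact episode. The
#: closed-form rate does not specify the particles' kinetics or the episode
#: definition; this closure window (40 s at the default dt) merges the rapid
#: re-contacts of the diffusive relative motion into single collision events
#: and was calibrated once against the analytic rate at N = 10, then
#: validated without further adjustment at N = 5 and N = 20 (docs/methods.md).
RIGID_HYSTERESIS_FRAMES = 8


def simulate_rigid_particles(
    params: CollisionModelParams = DEFAULT_PARAMS,
    N: int = 10,
    duration_h: float = 1.0,
    dt_s: float = RIGID_DT_S,
    seed: int = 0,
    heading_persistence_s: float = RIGID_HEADING_PERSISTENCE_S,
    hysteresis_frames: int = RIGID_HYSTERESIS_FRAMES,
    record_tracks: bool = False,
):
    """Monte-Carlo collision count of N hard disks in the circular arena.

    Disks of diameter L move at constant speed V inside a disk of area A;
    headings are redrawn uniformly at exponential intervals with mean
    ``heading_persistence_s``, and the arena wall reflects specularly. Disks
    are hard: overlaps created by a step are resolved by symmetric
    separation along the pair axis, which reproduces the excluded-area
    effect of the A - N*S denominator. A collision is one contact episode:
    it opens when a pair's centre distance first drops below L and closes
    after ``hysteresis_frames`` consecutive recorded frames at or above L.

    Returns the episode count, or ``(count, tracks)`` with
    ``record_tracks=True`` (tracks sampled every ``dt_s``).
    """
    if N < 0:
        raise ValueError("N must be non-negative")
    if N * params.S >= params.A:
        raise ValueError("arena over-packed")
    v_um_s = params.V / 3600.0
    if v_um_s * dt_s >= params.L / 2.0:
        raise ValueError("dt too coarse: particles could tunnel through contact")
    rng = np.random.default_rng(seed)
    arena_r = math.sqrt(params.A / math.pi)
    core_r = arena_r - params.L / 2.0  # wall constraint on centres
    L = params.L
    n_steps = int(round(duration_h * 3600.0 / dt_s))

    if N == 0:
        return (0, []) if record_tracks else 0

    # initial non-overlapping placement of centres in the core disk
    pos = np.empty((N, 2))
    count = 0
    attempts = 0
    while count < N:
        if attempts > 200_000:
            raise OverPackedError(f"cannot place {N} disks of diameter {L}")
        attempts += 1
        p = rng.uniform(-core_r, core_r, size=2)
        if np.linalg.norm(p) > core_r:
            continue
        if count and np.any(np.linalg.norm(pos[:count] - p, axis=1) < L):
            continue
        pos[count] = p
        count += 1

    heading = rng.uniform(0.0, 2.0 * math.pi, size=N)
    redraw_p = dt_s / heading_persistence_s

    in_episode = np.zeros((N, N), dtype=bool)
    apart_frames = np.zeros((N, N), dtype=int)
    n_episodes = 0
    iu, ju = np.triu_indices(N, k=1)
    history = [pos.copy()] if record_tracks else None

    for _ in range(n_steps):
        redraw = rng.random(N) < redraw_p
        if np.any(redraw):
            heading[redraw] = rng.uniform(0.0, 2.0 * math.pi, size=int(redraw.sum()))
        pos = pos + _unit(heading) * (v_um_s * dt_s)

        # wall: specular reflection of centres at the core radius
        r = np.linalg.norm(pos, axis=1)
        out = r > core_r
        if np.any(out):
            for k in np.flatnonzero(out):
                nrm = pos[k] / r[k]
                pos[k] = pos[k] - 2.0 * (r[k] - core_r) * nrm
                u = _unit(heading[[k]])[0]
                u = u - 2.0 * float(np.dot(u, nrm)) * nrm
                heading[k] = math.atan2(u[1], u[0])

        # hard-core: resolve overlaps by symmetric separation
        if N > 1:
            for _ in range(5):
                d = squareform(pdist(pos))
                oi, oj = np.nonzero(np.triu(d < L * (1.0 - 1e-9), k=1))
                if len(oi) == 0:
                    break
                for a, b in zip(oi, oj):
                    sep = pos[a] - pos[b]
                    dist = np.linalg.norm(sep)
                    if dist < 1e-9:
                        ang = rng.uniform(0.0, 2.0 * math.pi)
                        sep, dist = np.array([math.cos(ang), math.sin(ang)]), 1.0
                    push = (L * (1.0 - 1e-9) - dist) / 2.0
                    shift = sep / dist * push
                    pos[a] += shift
                    pos[b] -= shift
                # keep resolved centres inside the wall
                r = np.linalg.norm(pos, axis=1)
                over = r > core_r
                if np.any(over):
                    pos[over] *= (core_r / r[over])[:, None]

        # episode bookkeeping on the recorded frame positions
        if N > 1:
            d = squareform(pdist(pos))
            contact = d[iu, ju] < L
            for idx in np.flatnonzero(contact):
                a, b = iu[idx], ju[idx]
                if not in_episode[a, b]:
                    in_episode[a, b] = True
                    n_episodes += 1
                apart_frames[a, b] = 0
            for idx in np.flatnonzero(~contact):
                a, b = iu[idx], ju[idx]
                if in_episode[a, b]:
                    apart_frames[a, b] += 1
                    if apart_frames[a, b] >= hysteresis_frames:
                        in_episode[a, b] = False
                        apart_frames[a, b] = 0
        if record_tracks:
            history.append(pos.copy())

    if not record_tracks:
        return n_episodes
    arr = np.array(history)  # (frames, N, 2)
    frames = np.arange(arr.shape[0])
    tracks = [
        Track(
            track_id=k,
            frame=frames,
            t=frames * dt_s,
            x=arr[:, k, 0],
            y=arr[:, k, 1],
            radius=L / 2.0,
        )
        for k in range(N)
    ]
    return n_episodes, tracks


# ---------------------------------------------------------------------------
# Fixture presets
# ---------------------------------------------------------------------------


def _preset_fig3_division(seed: int) -> SimConfig:
    return SimConfig(
        region=Disk((0.0, 0.0), 50.0),
        n_cells=2,
        frame_interval=60.0,
        duration=12.0 * 3600.0,
        division=DivisionConfig(enabled=True),
        seed=seed,
    )


def _preset_fig4_collisions(seed: int) -> SimConfig:
    # 40% area density with the model's particle footprint (55.7 um^2)
    return SimConfig(
        region=Disk((0.0, 0.0), 50.0),
        n_cells=56,
        cell_radius=math.sqrt(55.7 / math.pi),
        duration=1800.0,
        seed=seed,
    )


def _preset_fig5_boundary(seed: int) -> SimConfig:
    # arc-boundary scenario: disk of radius 100 um
    return SimConfig(
        region=Disk((0.0, 0.0), 100.0),
        n_cells=8,
        duration=3600.0,
        seed=seed,
    )


FIXTURE_PRESETS = {
    "fig3_division": _preset_fig3_division,
    "fig4_collisions": _preset_fig4_collisions,
    "fig5_boundary": _preset_fig5_boundary,
    "lattice_single_cells": None,  # special-cased: one cell per lattice square
}


def generate_fixture(name: str, out_dir, seed: int = 0) -> dict:
    """Write a named synthetic scenario (tracks, lineage, region, manifest).

    Presets: ``fig3_division`` (dividing cells in the 100-um disk),
    ``fig4_collisions`` (40% area density, frequent contacts),
    ``fig5_boundary`` (boundary encounters at a 100-um-radius arc),
    ``lattice_single_cells`` (one cell per 15-um lattice square).
    """
    from . import io as ctio  # deferred: io imports this module's containers

    if name not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(FIXTURE_PRESETS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if name == "lattice_single_cells":
        pitch, side, grid = 65.0, 15.0, 3
        tracks = []
        lineage = LineageTree()
        tid = 0
        for gy in range(grid):
            for gx in range(grid):
                corner = (gx * pitch, gy * pitch)
                cfg = SimConfig(
                    region=Rectangle(corner, side, side),
                    n_cells=1,
                    cell_radius=2.0,
                    duration=1800.0,
                    collisions_enabled=False,
                    seed=seed * 97 + tid,
                )
                res = simulate(cfg)
                tr = res.tracks[0]
                tr.track_id = tid
                tracks.append(tr)
                lineage.add_founder(tid)
                tid += 1
        region_dict = {
            "kind": "rectangle",
            "corner_um": [0.0, 0.0],
            "width_um": side,
            "height_um": side,
        }
        config_dict = {"preset": name, "lattice_pitch_um": pitch, "grid": grid}
    else:
        cfg = FIXTURE_PRESETS[name](seed)
        res = simulate(cfg)
        tracks, lineage = res.tracks, res.lineage
        region_dict = region_to_dict(cfg.region)
        config_dict = cfg.to_dict()

    tracks_path = out_dir / "tracks.tsv"
    lineage_path = out_dir / "lineage.tsv"
    region_path = out_dir / "region.json"
    ctio.write_tracks(tracks, tracks_path)
    ctio.write_lineage(lineage, lineage_path)
    region_path.write_text(json.dumps(region_dict, indent=2) + "\n")
    manifest = {
        "preset": name,
        "seed": seed,
        "config": config_dict,
        "files": {
            "tracks": tracks_path.name,
            "lineage": lineage_path.name,
            "region": region_path.name,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
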