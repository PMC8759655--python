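"""Tabular file formats and run configuration.

All tabular artifacts are TSV with unit-suffixed column headers
(``x_um``, ``t_s``, ``birth_s`` ...). Tracks and lineages round-trip
losslessly through :func:`write_tracks` / :func:`read_tracks` and
:func:`write_lineage` / :func:`read_lineage`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cell_sim import LineageNode, LineageTree, SimConfig, Track
from .geometry import Region, region_from_dict, region_to_dict

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_lineage",
    "write_lineage",
    "AnalysisConfig",
    "RunConfig",
    "load_run_config",
    "config_hash",
]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]
LINEAGE_COLUMNS = ["track_id", "parent_id", "birth_s", "rounding_s", "abscission_s"]


class TrackFormatError(ValueError):
    """Malformed track or lineage table."""


def write_tracks(tracks, path) -> None:
    """Write tracks as TSV (track_id, frame, t_s, x_um, y_um[, radius_um])."""
    rows = []
    has_radius = any(tr.radius is not None for tr in tracks)
    for tr in sorted(tracks, key=lambda t: t.track_id):
        for f, t, x, y in zip(tr.frame, tr.t, tr.x, tr.y):
            row = {
                "track_id": tr.track_id,
                "frame": int(f),
                "t_s": t,
                "x_um": x,
                "y_um": y,
            }
            if has_radius:
                row["radius_um"] = tr.radius if tr.radius is not None else np.nan
            rows.append(row)
    cols = TRACK_COLUMNS + (["radius_um"] if has_radius else [])
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_tracks(path) -> list[Track]:
    """Read a track TSV; malformed rows are reported with line numbers."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise TrackFormatError(f"{path}: duplicate (track_id, frame) at line(s) {lines}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_index()  # preserve file order to detect non-monotone frames
        frames = g["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            bad = int(g.index[np.flatnonzero(np.diff(frames) <= 0)[0] + 1]) + 2
            raise TrackFormatError(
                f"{path}: non-monotone frames in track {tid} at line {bad}"
            )
        radius = None
        if "radius_um" in g.columns and g["radius_um"].notna().all():
            radius = float(g["radius_um"].iloc[0])
        tracks.append(
            Track(
                track_id=int(tid),
                frame=frames,
                t=g["t_s"].to_numpy(float),
                x=g["x_um"].to_numpy(float),
                y=g["y_um"].to_numpy(float),
                radius=radius,
            )
        )
    return tracks


def write_lineage(lineage: LineageTree, path) -> None:
    rows = []
    for node in sorted(lineage.nodes.values(), key=lambda n: n.track_id):
        rows.append(
            {
                "track_id": node.track_id,
                "parent_id": node.parent_id if node.parent_id is not None else -1,
                "birth_s": node.birth_s,
                "rounding_s": node.rounding_s if node.rounding_s is not None else np.nan,
                "abscission_s": node.abscission_s
                if node.abscission_s is not None
                else np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=LINEAGE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_lineage(path) -> LineageTree:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    lineage = LineageTree()
    for _, row in df.iterrows():
        parent = int(row["parent_id"])
        node = LineageNode(
            track_id=int(row["track_id"]),
            parent_id=None if parent < 0 else parent,
            birth_s=float(row["birth_s"]),
            rounding_s=None if pd.isna(row["rounding_s"]) else float(row["rounding_s"]),
            abscission_s=None
            if pd.isna(row["abscission_s"])
            else float(row["abscission_s"]),
        )
        lineage.nodes[node.track_id] = node
    # reconstruct child links
    for node in lineage.nodes.values():
        if node.parent_id is not None:
            parent = lineage.nodes[node.parent_id]
            parent.child_ids = tuple(sorted((*parent.child_ids, node.track_id)))
    lineage.validate()
    return lineage


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Knobs of the analysis stages (defaults match the module defaults)."""

    contact_distance_um: Optional[float] = None  # default: 2 * cell radius
    hysteresis_frames: int = 2
    direction_window_s: float = 30.0
    pre_post_window_s: float = 120.0
    near_distance_um: Optional[float] = None  # default: cell radius
    follow_window_s: float = 120.0
    parallel_tolerance_deg: float = 30.0
    n_rings: int = 4
    grid_step_um: float = 0.5
    per_cell_area_um2: float = 0.32 * 7853.0 / 200.0
    arena_area_um2: float = 7853.0

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunConfig:
    """Top-level configuration of a full pipeline run."""

    region: Region
    simulation: SimConfig
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "confinetrack_out"
    seed: int = 0
    tracks_path: Optional[str] = None  # analysis-only mode: ingest these tracks
    lineage_path: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        region = region_from_dict(d["region"])
        sim_dict = dict(d.get("simulation", {}))
        sim_dict.setdefault("seed", d.get("seed", 0))
        sim_dict["region"] = region_to_dict(region)
        simulation = SimConfig.from_dict(sim_dict)
        analysis = AnalysisConfig.from_dict(d.get("analysis", {}))
        return cls(
            region=region,
            simulation=simulation,
            analysis=analysis,
            output_dir=d.get("output_dir", "confinetrack_out"),
            seed=d.get("seed", 0),
            tracks_path=d.get("tracks_path"),
            lineage_path=d.get("lineage_path"),
        )

    def to_dict(self) -> dict:
        return {
            "region": region_to_dict(self.region),
            "simulation": self.simulation.to_dict(),
            "analysis": dataclasses.asdict(self.analysis),
            "output_dir": self.output_dir,
            "seed": self.seed,
            "tracks_path": self.tracks_path,
            "lineage_path": self.lineage_path,
        }


def load_run_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration (schema-validated)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return RunConfig.from_dict(data)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the scientific configuration (file locations excluded),
    for the run manifest."""
    d = config.to_dict()
    for key in ("output_dir", "tracks_path", "lineage_path"):
        d.pop(key, None)
    blob = json.dumps(d, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
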