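"""Time-averaged spatial occupancy in concentric rings of a disk.

The computational analogue of averaging a fluorescence timelapse: each
frame, the substrate points within a cell radius of any centroid count as
occupied; averaging over frames gives an occupancy map (fraction of time
covered), which is then summarised per concentric ring. Cells that follow
the pattern boundary show up as elevated occupancy in the outermost ring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cell_sim import Track
from .geometry import Disk

__all__ = [
    "RingPartition",
    "OccupancyProfile",
    "OccupancyMap",
    "rasterize_occupancy",
    "ring_means",
]


@dataclass(frozen=True)
class RingPartition:
    """Concentric rings tiling a disk, equal radial width by default."""

    center: tuple
    radius: float
    n_rings: int = 4
    equal_area: bool = False

    def edges(self) -> np.ndarray:
        """Ring edge radii, strictly increasing from 0 to radius."""
        if self.n_rings < 1:
            raise ValueError("need at least one ring")
        k = np.arange(self.n_rings + 1)
        if self.equal_area:
            return self.radius * np.sqrt(k / self.n_rings)
        return self.radius * k / self.n_rings

    @classmethod
    def for_disk(cls, disk: Disk, n_rings: int = 4, equal_area: bool = False):
        return cls(tuple(disk.center), disk.radius, n_rings, equal_area)


@dataclass
class OccupancyMap:
    """Per-grid-point fraction of frames occupied, on a square grid."""

    values: np.ndarray  # (ny, nx), NaN outside the disk
    xs: np.ndarray
    ys: np.ndarray
    grid_step: float
    disk: Disk
    n_frames: int


@dataclass
class OccupancyProfile:
    ring_edges: np.ndarray  # um
    ring_means: np.ndarray  # mean occupancy per ring, in [0, 1]
    ring_areas: np.ndarray  # grid-estimated ring areas, um^2

    @property
    def disk_mean(self) -> float:
        return float(
            np.sum(self.ring_means * self.ring_areas) / np.sum(self.ring_areas)
        )


def rasterize_occupancy(
    tracks: Sequence[Track],
    cell_radius: float,
    disk: Disk,
    grid_step: float = 0.5,
) -> OccupancyMap:
    """Occupancy map of a track set over a disk region.

    Grid points (spacing ``grid_step``) within ``cell_radius`` of any cell
    centre in a frame are occupied in that frame; the map holds per-point
    occupancy fractions over all frames. Frames are the union of all track
    frames (cells absent from a frame simply do not contribute).
    """
    if grid_step > cell_radius / 2.0:
        raise ValueError("grid_step must be <= cell_radius / 2 to resolve footprints")
    cx, cy = disk.center
    r = disk.radius
    xs = np.arange(cx - r, cx + r + grid_step / 2.0, grid_step)
    ys = np.arange(cy - r, cy + r + grid_step / 2.0, grid_step)
    gx, gy = np.meshgrid(xs, ys)
    inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2

    all_frames = sorted({int(f) for tr in tracks for f in tr.frame})
    hits = np.zeros(gx.shape, dtype=np.int64)
    if all_frames:
        # stamp a precomputed footprint around each centre, frame by frame
        rad_px = int(np.ceil(cell_radius / grid_step))
        offs = np.arange(-rad_px, rad_px + 1)
        ox, oy = np.meshgrid(offs, offs)
        stamp = (ox**2 + oy**2) * grid_step**2 <= cell_radius**2
        frame_index = {f: i for i, f in enumerate(all_frames)}
        positions: dict[int, list] = {f: [] for f in all_frames}
        for tr in tracks:
            for f, px, py in zip(tr.frame, tr.x, tr.y):
                positions[int(f)].append((px, py))
        ny, nx = gx.shape
        for f in all_frames:
            occ = np.zeros((ny, nx), dtype=bool)
            for px, py in positions[f]:
                ix = int(round((px - xs[0]) / grid_step))
                iy = int(round((py - ys[0]) / grid_step))
                x0, x1 = max(ix - rad_px, 0), min(ix + rad_px + 1, nx)
                y0, y1 = max(iy - rad_px, 0), min(iy + rad_px + 1, ny)
                sx0, sy0 = x0 - (ix - rad_px), y0 - (iy - rad_px)
                occ[y0:y1, x0:x1] |= stamp[sy0 : sy0 + (y1 - y0), sx0 : sx0 + (x1 - x0)]
            hits += occ
    values = np.where(inside, hits / max(len(all_frames), 1), np.nan)
    return OccupancyMap(values, xs, ys, grid_step, disk, len(all_frames))


def ring_means(occ_map: OccupancyMap, partition: RingPartition) -> OccupancyProfile:
    """Mean occupancy per concentric ring (area-normalised by construction)."""
    cx, cy = partition.center
    gx, gy = np.meshgrid(occ_map.xs, occ_map.ys)
    rad = np.hypot(gx - cx, gy - cy)
    edges = partition.edges()
    means = np.empty(partition.n_rings)
    areas = np.empty(partition.n_rings)
    cell_area = occ_map.grid_step**2
    for i in range(partition.n_rings):
        lo, hi = edges[i], edges[i + 1]
        sel = (rad >= lo) & (rad < hi if i < partition.n_rings - 1 else rad <= hi)
        sel &= ~np.isnan(occ_map.values)
        npts = int(sel.sum())
        if npts == 0:
            raise ValueError(
                f"ring [{lo:.2f}, {hi:.2f}) um contains no grid points; grid too coarse"
            )
        means[i] = float(np.nanmean(occ_map.values[sel]))
        areas[i] = npts * cell_area
    return OccupancyProfile(edges, means, areas)
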