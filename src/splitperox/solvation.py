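"""Active-site accessibility via solvation-shell statistics.

Quantifies how accessible a region (the heme group, the distal catalytic
histidine side chain, the heme iron) is to solvent by counting, frame by
frame, the water oxygens whose minimum distance to any atom of the
target is within a radius ("within" semantics — minimum distance to any
target atom, not to the centre of mass).  A voxel occupancy grid records
where around the region water resides, as the fraction of frames each
voxel holds at least one water oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import AtomSelection, Trajectory

__all__ = [
    "SolvationSeries",
    "OccupancyGrid",
    "count_waters_within",
    "solvation_series",
    "occupancy_grid",
    "his_sidechain_selection",
]

_SIDECHAIN_EXCLUDE = {"N", "CA", "C", "O", "H", "HA"}


@dataclass
class SolvationSeries:
    counts: np.ndarray
    label: str
    radius: float

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    @property
    def sd(self) -> float:
        return float(self.counts.std(ddof=1)) if len(self.counts) > 1 else 0.0

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"frame": np.arange(len(self.counts)), "n_waters": self.counts})
        with open(path, "w") as fh:
            fh.write(
                f"# waters within {self.radius} A of {self.label}: "
                f"mean={self.mean:.3f} sd={self.sd:.3f}\n"
            )
            df.to_csv(fh, sep="\t", index=False)


@dataclass
class OccupancyGrid:
    origin: np.ndarray
    voxel: float
    occupancy: np.ndarray  # (nx, ny, nz) fractions in [0, 1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    def write_dx(self, path: str | Path) -> None:
        """Write an OpenDX-style scalar grid for visualisation."""
        nx, ny, nz = self.shape
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write("origin {:.3f} {:.3f} {:.3f}\n".format(*self.origin))
            fh.write(f"delta {self.voxel:.3f} 0 0\n")
            fh.write(f"delta 0 {self.voxel:.3f} 0\n")
            fh.write(f"delta 0 0 {self.voxel:.3f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(
                f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
            )
            flat = self.occupancy.ravel(order="C")
            for i in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.4f}" for v in flat[i : i + 3]) + "\n")


def _min_dists(
    water_coords: np.ndarray, target_coords: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Minimum distance of each water to any target atom (min-image if box)."""
    diff = water_coords[:, None, :] - target_coords[None, :, :]
    if box is not None:
        box = np.asarray(box, dtype=float)
        diff -= box * np.round(diff / box)
    return np.sqrt(np.sum(diff**2, axis=2)).min(axis=1)


def count_waters_within(
    frame_coords: np.ndarray,
    water_selection: AtomSelection,
    target_selection: AtomSelection,
    radius: float,
    box: np.ndarray | None = None,
) -> int:
    """Waters whose minimum distance to any target atom is <= radius.

    The minimum-image convention is applied for an orthorhombic ``box``;
    plain Euclidean distances otherwise.
    """
    if len(target_selection) == 0:
        raise ValueError("empty target selection")
    if len(water_selection) == 0:
        return 0
    coords = np.asarray(frame_coords, dtype=float)
    d = _min_dists(
        coords[water_selection.indices], coords[target_selection.indices], box
    )
    return int(np.sum(d <= radius))


def solvation_series(
    traj: Trajectory,
    water_selection: AtomSelection,
    target_selection: AtomSelection,
    radius: float = 5.0,
    label: str | None = None,
) -> SolvationSeries:
    """Per-frame water counts around a target plus mean +/- SD over frames.

    The 5 A default radius is the counting shell used for the heme
    group, the distal His side chain and the Fe ion.
    """
    if len(target_selection) == 0:
        raise ValueError("empty target selection")
    counts = np.empty(traj.n_frames, dtype=int)
    for t in range(traj.n_frames):
        box = None
        if traj.box_per_frame is not None:
            box = traj.box_per_frame[t]
        elif traj.atom_table.box is not None:
            box = traj.atom_table.box
        counts[t] = count_waters_within(
            traj.frames[t], water_selection, target_selection, radius, box
        )
    return SolvationSeries(
        counts=counts,
        label=label or target_selection.label or "target",
        radius=float(radius),
    )


def his_sidechain_selection(traj_or_struct, res_seq: int = 42) -> AtomSelection:
    """Side-chain atoms of a histidine residue (backbone excluded)."""
    from .structure_io import _table, select

    table = _table(traj_or_struct)
    his = select(traj_or_struct, res_names=["HIS"], res_seqs=[res_seq]).indices
    side = his[~np.isin(table.name[his], sorted(_SIDECHAIN_EXCLUDE))]
    return AtomSelection(indices=side, label=f"His{res_seq}_sidechain")


def occupancy_grid(
    traj: Trajectory,
    water_selection: AtomSelection,
    region_selection: AtomSelection,
    shell_radius: float = 3.0,
    voxel: float = 0.5,
) -> OccupancyGrid:
    """Fraction of frames each voxel near a region holds a water oxygen.

    The grid spans the region selection's frame-0 bounding box expanded
    by ``shell_radius``; voxels farther than ``shell_radius`` from every
    region atom (frame 0) are masked to zero.  The trajectory should be
    aligned first so the region is stationary.
    """
    if len(region_selection) == 0:
        raise ValueError("empty region selection")
    region0 = traj.frames[0, region_selection.indices]
    span = region0.max(axis=0) - region0.min(axis=0)
    if np.all(span < 1e-9) and len(region0) < 2:
        pass  # a single-atom region is fine; degenerate only if empty
    origin = region0.min(axis=0) - shell_radius
    extent = region0.max(axis=0) + shell_radius - origin
    dims = np.maximum(np.ceil(extent / voxel).astype(int), 1)
    hit_frames = np.zeros(tuple(dims), dtype=int)
    water_idx = water_selection.indices
    for t in range(traj.n_frames):
        w = traj.frames[t, water_idx]
        ijk = np.floor((w - origin) / voxel).astype(int)
        inside = np.all((ijk >= 0) & (ijk < dims), axis=1)
        ijk = np.unique(ijk[inside], axis=0)
        if len(ijk):
            hit_frames[ijk[:, 0], ijk[:, 1], ijk[:, 2]] += 1
    occupancy = hit_frames / traj.n_frames
    # mask voxels outside the shell of the region (voxel centres)
    centers = [
        origin[d] + (np.arange(dims[d]) + 0.5) * voxel for d in range(3)
    ]
    gx, gy, gz = np.meshgrid(*centers, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    min_d = np.full(len(pts), np.inf)
    for atom in region0:
        min_d = np.minimum(min_d, np.linalg.norm(pts - atom, axis=1))
    mask = (min_d <= shell_radius).reshape(tuple(dims))
    occupancy = np.where(mask, occupancy, 0.0)
    return OccupancyGrid(origin=origin, voxel=float(voxel), occupancy=occupancy)
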