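"""Trajectory stability statistics.

Four statistics quantify how much a protein moves over a trajectory:

* an RMSD time series versus a reference conformation,
* per-residue RMSF (root-mean-square fluctuation of the C-alpha about
  its time-averaged position),
* the trajectory map — a frames x residues matrix of each residue's
  mass-weighted backbone centre-of-mass displacement from its position
  in the starting frame of the aligned trajectory,
* the windowed mean backbone displacement (mean +/- SD over a frame
  window of the per-frame residue-mean displacement).

Note the two deliberately different references: the trajectory map
measures displacement from the *starting* conformation, while RMSF by
default fluctuates about the *mean* structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import atom_weights

from .structure_io import (
    AtomSelection,
    BACKBONE_NAMES,
    Structure,
    Trajectory,
    select_calpha,
)
from .superposition import kabsch_fit

__all__ = [
    "RMSFProfile",
    "TrajMapMatrix",
    "WindowedDisplacement",
    "rmsd_series",
    "rmsf",
    "trajectory_map",
    "windowed_mean_displacement",
    "last_fraction_window",
]


@dataclass
class RMSFProfile:
    residue_numbers: np.ndarray
    rmsf: np.ndarray
    reference: str = "mean"

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"residue": self.residue_numbers, "rmsf_A": np.round(self.rmsf, 3)})
        with open(path, "w") as fh:
            fh.write(f"# per-residue RMSF (A), reference={self.reference}\n")
            df.to_csv(fh, sep="\t", index=False)


@dataclass
class TrajMapMatrix:
    """Frames x residues matrix of backbone-COM displacements (A)."""

    displacement: np.ndarray
    residue_numbers: np.ndarray
    times: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.displacement.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            np.round(self.displacement, 3),
            columns=[str(r) for r in self.residue_numbers],
        )
        df.insert(0, "frame", np.arange(self.n_frames))
        with open(path, "w") as fh:
            fh.write("# trajectory map: backbone-COM displacement from frame 0 (A)\n")
            df.to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class WindowedDisplacement:
    window: tuple[int, int]
    mean: float
    sd: float
    n_frames: int
    n_residues: int


def rmsd_series(
    traj: Trajectory,
    reference: int | Structure = 0,
    selection: AtomSelection | None = None,
    fit: bool = False,
) -> np.ndarray:
    """Per-frame RMSD (A) versus a reference over a selection.

    The trajectory is assumed already aligned; pass ``fit=True`` to
    least-squares fit each frame on the selection before measuring.
    """
    if selection is None:
        selection = select_calpha(traj)
    if len(selection) == 0:
        raise ValueError("empty selection")
    idx = selection.indices
    if isinstance(reference, Structure):
        ref = reference.coords[idx]
    else:
        ref = traj.frames[int(reference), idx]
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame = traj.frames[t, idx]
        if fit:
            out[t] = kabsch_fit(frame, ref).rmsd
        else:
            out[t] = np.sqrt(np.mean(np.sum((frame - ref) ** 2, axis=1)))
    return out


def rmsf(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    reference: str = "mean",
) -> RMSFProfile:
    """Per-residue RMSF of the representative atom (default C-alpha).

    RMSF_i = sqrt(mean over frames of |x_i(t) - ref_i|^2), with the
    reference position the time average (``reference='mean'``) or the
    first frame (``'frame0'``).  A single-frame trajectory yields an
    all-zero profile with a warning.  When the selection holds several
    atoms of one residue their RMSF values are averaged.
    """
    if reference not in ("mean", "frame0"):
        raise ValueError("reference must be 'mean' or 'frame0'")
    if selection is None:
        selection = select_calpha(traj)
    if len(selection) == 0:
        raise ValueError("empty selection")
    if traj.n_frames < 2:
        warnings.warn("single-frame trajectory: RMSF is identically zero", stacklevel=2)
    idx = selection.indices
    coords = traj.frames[:, idx]  # (T, n, 3)
    ref = coords.mean(axis=0) if reference == "mean" else coords[0]
    per_atom = np.sqrt(np.mean(np.sum((coords - ref) ** 2, axis=2), axis=0))
    table = traj.atom_table
    groups = table.residue_groups(idx)
    res_numbers = np.array([res for (_, res), _ in groups], dtype=int)
    pos_of = {int(i): k for k, i in enumerate(idx)}
    values = np.array(
        [np.mean([per_atom[pos_of[int(i)]] for i in grp]) for _, grp in groups]
    )
    return RMSFProfile(residue_numbers=res_numbers, rmsf=values, reference=reference)


def _atom_mass(element: str) -> float:
    return float(atom_weights.get(element.capitalize(), 12.011))


def trajectory_map(traj: Trajectory) -> TrajMapMatrix:
    """Backbone-COM displacement of every polymer residue from frame 0.

    Entry (t, i) is the Euclidean distance between the mass-weighted
    centre of mass of residue i's backbone (N, CA, C, O) in frame t and
    in frame 0.  The trajectory should already be aligned (C-alpha on
    frame 0) so that rigid-body motion does not masquerade as residue
    displacement.  Residues missing some backbone atoms use the
    available subset with a warning; residues with none give NaN.
    """
    table = traj.atom_table
    polymer = np.nonzero(~table.is_hetero)[0]
    groups = table.residue_groups(polymer)
    res_numbers = np.array([res for (_, res), _ in groups], dtype=int)
    n_res = len(groups)
    disp = np.full((traj.n_frames, n_res), np.nan)
    incomplete: list[int] = []
    for col, ((_, res), grp) in enumerate(groups):
        bb = grp[np.isin(table.name[grp], BACKBONE_NAMES)]
        if len(bb) == 0:
            warnings.warn(f"residue {res}: no backbone atoms, NaN column", stacklevel=2)
            continue
        if len(bb) < len(BACKBONE_NAMES):
            incomplete.append(res)
        masses = np.array([_atom_mass(table.element[i]) for i in bb])
        w = masses / masses.sum()
        com = np.einsum("a,tax->tx", w, traj.frames[:, bb])
        disp[:, col] = np.linalg.norm(com - com[0], axis=1)
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} residue(s) with incomplete backbone used the "
            f"available subset: {incomplete[:10]}",
            stacklevel=2,
        )
    return TrajMapMatrix(displacement=disp, residue_numbers=res_numbers, times=traj.times)


def last_fraction_window(n_frames: int, fraction: float = 0.4) -> tuple[int, int]:
    """The frame window covering the last ``fraction`` of a trajectory."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    start = int(np.ceil(n_frames * (1.0 - fraction)))
    return (min(start, n_frames - 1), n_frames)


def windowed_mean_displacement(
    trajmap: TrajMapMatrix,
    frame_window: tuple[int, int],
    pooled_sd: bool = False,
) -> WindowedDisplacement:
    """Mean +/- SD backbone displacement over a frame window.

    For each frame in ``[start, stop)`` the mean displacement over
    residues is taken (NaN residues excluded); the reported statistics
    are the mean and sample SD of that per-frame series.  With
    ``pooled_sd=True`` the SD is instead over all residue-frame entries
    in the window.
    """
    start, stop = frame_window
    if not (0 <= start < stop <= trajmap.n_frames):
        raise ValueError(f"window {frame_window} outside 0..{trajmap.n_frames}")
    block = trajmap.displacement[start:stop]
    valid_cols = ~np.all(np.isnan(block), axis=0)
    per_frame = np.nanmean(block[:, valid_cols], axis=1)
    mean = float(per_frame.mean())
    if pooled_sd:
        sd = float(np.nanstd(block[:, valid_cols], ddof=1)) if block.size > 1 else 0.0
    else:
        sd = float(per_frame.std(ddof=1)) if len(per_frame) > 1 else 0.0
    return WindowedDisplacement(
        window=(start, stop),
        mean=mean,
        sd=sd,
        n_frames=stop - start,
        n_residues=int(valid_cols.sum()),
    )
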