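"""Essential dynamics: PCA of aligned coordinates and gromos clustering.

PCA (essential dynamics) diagonalises the covariance of the flattened
C-alpha coordinates of an aligned trajectory about their time mean; the
leading eigenvectors are the collective motions that dominate the
fluctuations and the per-component explained fraction is eigenvalue /
trace.  To compare a split variant with its wild type in one plane, the
variant's frames are projected onto the wild type's components over the
shared residue set.

The clustering is the standard neighbour-counting (gromos) scheme:
the frame with the most neighbours within an RMSD cutoff seeds a
cluster containing it and its neighbours, those frames are removed, and
the procedure repeats.  The representative of a cluster is its medoid —
the member with minimum mean RMSD to the other members — which realises
the "middle structure" used for snapshot rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import AtomSelection, Structure, Trajectory, select_calpha
from .superposition import kabsch_fit

__all__ = [
    "PCAResult",
    "ClusteringResult",
    "pca",
    "project_onto",
    "joint_pca",
    "gromos_cluster",
    "shared_calpha_selections",
    "pairwise_rmsd_matrix",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # all eigenvalues, descending, A^2
    eigenvectors: np.ndarray  # (3n, k) orthonormal columns
    explained_fraction: np.ndarray  # per eigenvalue
    projections: np.ndarray  # (n_frames, k), A
    mean: np.ndarray  # (3n,)
    k: int

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "eigenvalue_A2": np.round(self.eigenvalues, 6),
                "explained_fraction": np.round(self.explained_fraction, 6),
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# PCA spectrum, k={self.k} components retained\n")
            df.to_csv(fh, sep="\t", index=False)


@dataclass
class ClusteringResult:
    labels: np.ndarray  # per-frame cluster index (0 = largest)
    sizes: np.ndarray  # descending
    representatives: np.ndarray  # frame index per cluster
    rmsd_cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"frame": np.arange(len(self.labels)), "cluster": self.labels})
        with open(path, "w") as fh:
            fh.write(
                f"# gromos clustering, cutoff={self.rmsd_cutoff} A, "
                f"sizes={list(map(int, self.sizes))}, "
                f"representatives={list(map(int, self.representatives))}\n"
            )
            df.to_csv(fh, sep="\t", index=False)


def _flatten(traj: Trajectory, selection: AtomSelection) -> np.ndarray:
    return traj.frames[:, selection.indices].reshape(traj.n_frames, -1)


def pca(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    k: int = 2,
) -> PCAResult:
    """Essential-dynamics PCA of an aligned trajectory.

    Sample covariance (about the time mean) of the flattened selection
    coordinates, eigendecomposed; projections of every frame onto the
    top-``k`` components are returned along with the full spectrum.
    Covariance is not mass-weighted.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if selection is None:
        selection = select_calpha(traj)
    if len(selection) == 0:
        raise ValueError("empty selection")
    x = _flatten(traj, selection)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    k = min(k, evecs.shape[1])
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    projections = xc @ evecs[:, :k]
    return PCAResult(
        eigenvalues=evals,
        eigenvectors=evecs[:, :k],
        explained_fraction=frac,
        projections=projections,
        mean=mean,
        k=k,
    )


def shared_calpha_selections(
    a: Structure | Trajectory, b: Structure | Trajectory
) -> tuple[AtomSelection, AtomSelection]:
    """C-alpha selections over the residue numbers common to two systems."""
    from .structure_io import _table

    sel_a = select_calpha(a).indices
    sel_b = select_calpha(b).indices
    ta, tb = _table(a), _table(b)
    num_a = {int(ta.res_seq[i]): i for i in sel_a}
    num_b = {int(tb.res_seq[i]): i for i in sel_b}
    shared = sorted(set(num_a) & set(num_b))
    return (
        AtomSelection(np.array([num_a[r] for r in shared], dtype=int), "shared_calpha"),
        AtomSelection(np.array([num_b[r] for r in shared], dtype=int), "shared_calpha"),
    )


def project_onto(
    pca_result: PCAResult,
    other_traj: Trajectory,
    shared_selection: AtomSelection,
) -> np.ndarray:
    """Project another system's frames onto a reference system's components.

    ``shared_selection`` picks the atoms of ``other_traj`` that map
    one-to-one (by residue number) onto the atom set the reference PCA
    was computed on; centring uses the *reference* mean so the two
    systems share an origin in the PC1-PC2 plane.
    """
    if len(shared_selection) == 0:
        raise ValueError("no shared atoms")
    y = _flatten(other_traj, shared_selection)
    if y.shape[1] != pca_result.eigenvectors.shape[0]:
        raise ValueError(
            f"shared selection gives {y.shape[1]} coordinates but the reference "
            f"PCA has {pca_result.eigenvectors.shape[0]}"
        )
    return (y - pca_result.mean) @ pca_result.eigenvectors


def joint_pca(
    traj_a: Trajectory,
    traj_b: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    k: int = 2,
) -> tuple[PCAResult, np.ndarray, np.ndarray]:
    """Alternative cross-system scheme: PCA of the concatenated trajectories.

    Returns the joint result plus each system's projections.
    """
    xa = _flatten(traj_a, sel_a)
    xb = _flatten(traj_b, sel_b)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("selections must give equal coordinate counts")
    x = np.vstack([xa, xb])
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (len(x) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(k, evecs.shape[1])
    frac = evals / evals.sum() if evals.sum() > 0 else np.zeros_like(evals)
    result = PCAResult(
        eigenvalues=evals,
        eigenvectors=evecs[:, :k],
        explained_fraction=frac,
        projections=xc[: len(xa)] @ evecs[:, :k],
        mean=mean,
        k=k,
    )
    return result, result.projections, xc[len(xa) :] @ evecs[:, :k]


def pairwise_rmsd_matrix(
    traj: Trajectory, selection: AtomSelection | None = None, fit: bool = True
) -> np.ndarray:
    """Symmetric matrix of pairwise frame RMSDs (per-pair Kabsch fit by default)."""
    if selection is None:
        selection = select_calpha(traj)
    coords = traj.frames[:, selection.indices]
    n = traj.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if fit:
                mat[i, j] = kabsch_fit(coords[j], coords[i]).rmsd
            else:
                mat[i, j] = np.sqrt(np.mean(np.sum((coords[j] - coords[i]) ** 2, axis=1)))
            mat[j, i] = mat[i, j]
    return mat


def gromos_cluster(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    rmsd_cutoff: float = 1.0,
    fit: bool = True,
) -> ClusteringResult:
    """Neighbour-counting conformational clustering.

    Iteratively: count each remaining frame's neighbours within
    ``rmsd_cutoff``; the frame with most neighbours (ties broken by the
    lowest frame index) seeds a cluster of itself plus its neighbours;
    remove them and repeat.  Labels are reassigned so cluster 0 is the
    most populated; each cluster's representative is its medoid.
    """
    if selection is None:
        selection = select_calpha(traj)
    mat = pairwise_rmsd_matrix(traj, selection, fit=fit)
    n = traj.n_frames
    remaining = np.ones(n, dtype=bool)
    raw_clusters: list[np.ndarray] = []
    while remaining.any():
        idx = np.nonzero(remaining)[0]
        sub = mat[np.ix_(idx, idx)]
        neighbor_counts = np.sum(sub <= rmsd_cutoff, axis=1) - 1
        seed_local = int(np.argmax(neighbor_counts))  # argmax takes lowest index on ties
        seed = idx[seed_local]
        members = idx[sub[seed_local] <= rmsd_cutoff]  # includes the seed itself
        raw_clusters.append(members)
        remaining[members] = False
    order = sorted(
        range(len(raw_clusters)),
        key=lambda c: (-len(raw_clusters[c]), int(raw_clusters[c].min())),
    )
    labels = np.empty(n, dtype=int)
    sizes = []
    reps = []
    for new_label, c in enumerate(order):
        members = raw_clusters[c]
        labels[members] = new_label
        sizes.append(len(members))
        if len(members) == 1:
            reps.append(int(members[0]))
        else:
            sub = mat[np.ix_(members, members)]
            mean_to_others = sub.sum(axis=1) / (len(members) - 1)
            reps.append(int(members[np.argmin(mean_to_others)]))
    return ClusteringResult(
        labels=labels,
        sizes=np.asarray(sizes, dtype=int),
        representatives=np.asarray(reps, dtype=int),
        rmsd_cutoff=float(rmsd_cutoff),
    )
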