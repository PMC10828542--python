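"""Optimal rigid-body superposition (Kabsch) and trajectory alignment.

The Kabsch algorithm finds the proper rotation and translation that
minimise the (weighted) RMSD between two paired point sets; a sign
correction on the smallest singular value excludes reflections.  The
same fit drives structure-vs-structure superposition on paired C-alpha
atoms and least-squares alignment of every trajectory frame to a
reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_features import global_alignment
from .structure_io import (
    AtomSelection,
    Structure,
    Trajectory,
    extract_sequence,
    select_calpha,
)

__all__ = [
    "FitResult",
    "kabsch_fit",
    "rmsd",
    "superpose_structures",
    "align_trajectory",
]


@dataclass(frozen=True)
class FitResult:
    """A rigid-body fit: ``y = rotation @ x + translation`` maps mobile onto target."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int = 0

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "rmsd": self.rmsd,
                "n_pairs": self.n_pairs,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Plain (no fitting) weighted RMSD between paired coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    sq = np.sum((a - b) ** 2, axis=1)
    if weights is None:
        return float(np.sqrt(sq.mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt(np.sum(w * sq) / np.sum(w)))


def _check_not_degenerate(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    # collinear points have rank <= 1 after centering
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set; cannot fit rotation")


def kabsch_fit(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Least-squares rigid fit of ``mobile`` onto ``target``.

    Both inputs are (n, 3) arrays with n >= 3 non-collinear points in
    corresponding order.  Returns the proper rotation (det +1),
    translation and the residual RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    _check_not_degenerate(mobile)
    _check_not_degenerate(target)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm = w @ mobile
    ct = w @ target
    p = mobile - cm
    q = target - ct
    h = (p * w[:, None]).T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    fitted = p @ rot.T
    residual = float(np.sqrt(np.sum(w * np.sum((fitted - q) ** 2, axis=1))))
    translation = ct - rot @ cm
    return FitResult(rotation=rot, translation=translation, rmsd=residual, n_pairs=n)


def _paired_calpha_indices(
    struct_a: Structure,
    struct_b: Structure,
    pairing: str,
    chain_a: str | None,
    chain_b: str | None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    ca_a = select_calpha(struct_a, chain=chain_a).indices
    ca_b = select_calpha(struct_b, chain=chain_b).indices
    num_a = {int(struct_a.res_seq[i]): i for i in ca_a}
    num_b = {int(struct_b.res_seq[i]): i for i in ca_b}
    pairs: list[tuple[int, int]] = []
    if pairing == "by_resseq":
        for res in sorted(set(num_a) & set(num_b)):
            pairs.append((res, res))
    elif pairing == "by_seq_align":
        chain_a_id = chain_a or str(struct_a.chain[ca_a[0]]) if len(ca_a) else "A"
        chain_b_id = chain_b or str(struct_b.chain[ca_b[0]]) if len(ca_b) else "A"
        seq_a, map_a = extract_sequence(struct_a, chain_a_id, use_seqres=False)
        seq_b, map_b = extract_sequence(struct_b, chain_b_id, use_seqres=False)
        gapped_a, gapped_b, _ = global_alignment(seq_a, seq_b)
        ia = ib = 0
        for ca_char, cb_char in zip(gapped_a, gapped_b):
            if ca_char != "-" and cb_char != "-":
                pairs.append((map_a[ia], map_b[ib]))
            if ca_char != "-":
                ia += 1
            if cb_char != "-":
                ib += 1
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    pairs = [(ra, rb) for ra, rb in pairs if ra in num_a and rb in num_b]
    idx_a = np.array([num_a[ra] for ra, _ in pairs], dtype=int)
    idx_b = np.array([num_b[rb] for _, rb in pairs], dtype=int)
    return idx_a, idx_b, pairs


def superpose_structures(
    struct_a: Structure,
    struct_b: Structure,
    pairing: str = "by_seq_align",
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> tuple[FitResult, list[tuple[int, int]]]:
    """Superpose ``struct_a`` onto ``struct_b`` over paired C-alpha atoms.

    ``pairing='by_resseq'`` pairs identical residue numbers;
    ``'by_seq_align'`` pairs aligned non-gap columns of a global sequence
    alignment.  Returns the fit plus the (res_a, res_b) pair list.
    """
    idx_a, idx_b, pairs = _paired_calpha_indices(
        struct_a, struct_b, pairing, chain_a, chain_b
    )
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 paired C-alpha atoms, got {len(pairs)}")
    fit = kabsch_fit(struct_a.coords[idx_a], struct_b.coords[idx_b])
    return fit, pairs


def align_trajectory(
    traj: Trajectory,
    reference: int | Structure = 0,
    selection: AtomSelection | None = None,
) -> Trajectory:
    """Least-squares fit every frame to a reference on a selection.

    Default reference is frame 0 and default selection the polymer
    C-alpha atoms; the fitted rigid transform of each frame is applied
    to *all* atoms of that frame.
    """
    if selection is None:
        selection = select_calpha(traj)
    if len(selection) == 0:
        raise ValueError("empty alignment selection")
    idx = selection.indices
    if isinstance(reference, Structure):
        if len(reference) != traj.n_atoms:
            raise ValueError("reference structure atom count differs from trajectory")
        ref_coords = reference.coords[idx]
    else:
        ref_coords = traj.frames[int(reference), idx]
    out = np.empty_like(traj.frames)
    for t in range(traj.n_frames):
        fit = kabsch_fit(traj.frames[t, idx], ref_coords)
        out[t] = fit.transform(traj.frames[t])
    return traj.with_frames(out)
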