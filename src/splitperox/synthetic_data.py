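"""Synthetic structures and trajectories with known ground truth.

Every analysis stage in this package is exercised against data whose
true answer is known by construction: an ideal helical fold, per-residue
isotropic Gaussian fluctuations of chosen amplitude (under which RMSF,
trajectory maps and PCA spectra have closed forms — e.g. RMSF converges
to sigma*sqrt(3)), optional per-frame rigid-body motion that alignment
must remove exactly, and water particles planted at controlled minimum
distances from chosen atom groups so shell counts are known per frame.

``make_peroxidase_model`` builds a schematic, clearly *synthetic*
stand-in for a peroxidase crystal structure: a real sequence threaded
onto an ideal helix, with cysteine SG atoms placed at bonding distance
for chosen disulfide pairs, a minimal heme group whose Fe sits at
coordinate-bond distance from a chosen proximal histidine, and
monoatomic calcium ions.  Its geometry is not physical; it exists so the
feature detectors can be tested against planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.SeqUtils import seq3 as _seq3

from .structure_io import AtomSelection, Structure, Trajectory

__all__ = [
    "SyntheticSpec",
    "GroundTruthManifest",
    "WaterPlan",
    "make_helix",
    "make_trajectory",
    "plant_waters",
    "make_peroxidase_model",
]

_HELIX_RISE = 1.5  # A per residue
_HELIX_TWIST = 100.0  # degrees per residue
_HELIX_RADIUS = 2.3  # A

# fixed local offsets of the pseudo-backbone atoms from each C-alpha (A)
_BACKBONE_OFFSETS = {
    "N": np.array([-0.9, 0.8, -0.9]),
    "C": np.array([0.9, 0.8, 0.9]),
    "O": np.array([1.1, 1.9, 1.1]),
}


@dataclass
class SyntheticSpec:
    """Recipe for a Gaussian-fluctuation trajectory.

    ``sigma`` is the per-coordinate fluctuation amplitude in Angstrom,
    either a scalar or one value per residue.  ``rot_deg`` and
    ``trans_ang`` are the standard deviations of the per-frame global
    rigid rotation angle (degrees, random axis, about the centroid) and
    translation (A per component).  A fixed seed gives bitwise-identical
    output.
    """

    n_frames: int
    sigma: float | Sequence[float] = 0.5
    rot_deg: float = 0.0
    trans_ang: float = 0.0
    seed: int = 0

    def sigma_per_residue(self, n_residues: int) -> np.ndarray:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim == 0:
            s = np.full(n_residues, float(s))
        if s.shape != (n_residues,):
            raise ValueError(f"sigma must be scalar or length {n_residues}")
        if np.any(s < 0):
            raise ValueError("sigma must be non-negative")
        return s


@dataclass
class GroundTruthManifest:
    """Everything planted into a synthetic trajectory, for oracle checks."""

    seed: int
    sigma_per_residue: np.ndarray | None = None
    rotations: np.ndarray | None = None  # (n_frames, 3, 3)
    translations: np.ndarray | None = None  # (n_frames, 3)
    water_counts: dict[str, np.ndarray] = field(default_factory=dict)


def make_helix(n_residues: int, sequence: str | None = None, chain: str = "A") -> Structure:
    """Ideal alpha-helical C-alpha trace with pseudo-backbone N, C, O atoms.

    Rise 1.5 A and 100 degrees of twist per residue on a 2.3 A radius,
    which reproduces the ~3.8 A consecutive C-alpha spacing of real
    helices.  Residues are poly-Ala unless ``sequence`` overrides them
    (e.g. to plant sequons or cysteines).
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if sequence is not None:
        if len(sequence) != n_residues:
            raise ValueError("sequence length must equal n_residues")
        res_names = [_seq3(aa).upper() for aa in sequence]
    else:
        res_names = ["ALA"] * n_residues
    names, elements, res_name_arr, res_seq_arr, coords = [], [], [], [], []
    for i in range(n_residues):
        theta = np.deg2rad(_HELIX_TWIST * i)
        ca = np.array(
            [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i]
        )
        for atom_name in ("N", "CA", "C", "O"):
            names.append(atom_name)
            elements.append(atom_name[0])
            res_name_arr.append(res_names[i])
            res_seq_arr.append(i + 1)
            coords.append(ca if atom_name == "CA" else ca + _BACKBONE_OFFSETS[atom_name])
    n = len(names)
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.array(names, dtype="U6"),
        element=np.array(elements, dtype="U2"),
        res_name=np.array(res_name_arr, dtype="U5"),
        res_seq=np.array(res_seq_arr, dtype=int),
        chain=np.full(n, chain, dtype="U4"),
        is_hetero=np.zeros(n, dtype=bool),
        coords=np.asarray(coords, dtype=float),
        source_id="synthetic_helix",
    )


def _random_rotation(rng: np.random.Generator, angle_sd_deg: float) -> np.ndarray:
    if angle_sd_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, angle_sd_deg))
    kx, ky, kz = axis
    k_mat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * k_mat + (1 - np.cos(angle)) * (k_mat @ k_mat)


def make_trajectory(
    structure: Structure, spec: SyntheticSpec
) -> tuple[Trajectory, GroundTruthManifest]:
    """Gaussian-fluctuation trajectory over a structure.

    Frame t is ``R_t (x0 + eta_t - c) + c + T_t`` with per-atom
    isotropic Gaussian noise ``eta`` of the owning residue's sigma,
    rotation about the static centroid ``c``.  The manifest records the
    planted sigma profile and every applied rigid transform.
    """
    rng = np.random.default_rng(spec.seed)
    res_numbers = sorted({int(r) for r in structure.res_seq[~structure.is_hetero]})
    sigma_res = spec.sigma_per_residue(len(res_numbers))
    sigma_of = dict(zip(res_numbers, sigma_res))
    sigma_atom = np.array(
        [sigma_of.get(int(r), 0.0) if not h else 0.0
         for r, h in zip(structure.res_seq, structure.is_hetero)]
    )
    x0 = structure.coords
    centroid = x0.mean(axis=0)
    frames = np.empty((spec.n_frames, len(structure), 3))
    rotations = np.empty((spec.n_frames, 3, 3))
    translations = np.empty((spec.n_frames, 3))
    for t in range(spec.n_frames):
        eta = rng.normal(size=x0.shape) * sigma_atom[:, None]
        rot = _random_rotation(rng, spec.rot_deg)
        trans = (
            rng.normal(0.0, spec.trans_ang, size=3) if spec.trans_ang > 0 else np.zeros(3)
        )
        if spec.rot_deg == 0 and spec.trans_ang == 0:
            frames[t] = x0 + eta  # bitwise-static when sigma is zero too
        else:
            frames[t] = (x0 + eta - centroid) @ rot.T + centroid + trans
        rotations[t] = rot
        translations[t] = trans
    traj = Trajectory(atom_table=structure, frames=frames)
    manifest = GroundTruthManifest(
        seed=spec.seed,
        sigma_per_residue=sigma_res,
        rotations=rotations,
        translations=translations,
    )
    return traj, manifest


@dataclass
class WaterPlan:
    """Plant waters at controlled minimum distances from a target.

    ``inside_counts`` (scalar or per frame) waters get a minimum
    distance to the target inside ``inner_band`` (which must lie within
    ``shell_radius``); the remaining ``total - inside`` waters land in
    ``outer_band``, strictly beyond the shell.
    """

    target: AtomSelection
    shell_radius: float = 5.0
    inside_counts: int | Sequence[int] = 0
    total: int | None = None
    inner_band: tuple[float, float] | None = None
    outer_band: tuple[float, float] | None = None
    label: str = ""

    def resolve(self, n_frames: int) -> tuple[np.ndarray, int, tuple, tuple]:
        inside = np.asarray(self.inside_counts, dtype=int)
        if inside.ndim == 0:
            inside = np.full(n_frames, int(inside))
        if inside.shape != (n_frames,):
            raise ValueError("inside_counts must be scalar or one per frame")
        total = int(self.total) if self.total is not None else int(inside.max())
        if np.any(inside > total) or np.any(inside < 0):
            raise ValueError("inside counts must lie in [0, total]")
        inner = self.inner_band or (0.45 * self.shell_radius, 0.95 * self.shell_radius)
        outer = self.outer_band or (1.25 * self.shell_radius, 2.5 * self.shell_radius)
        if inner[1] > self.shell_radius:
            raise ValueError("inner band must lie within the shell radius")
        if outer[0] <= self.shell_radius:
            raise ValueError("outer band must lie beyond the shell radius")
        return inside, total, inner, outer


def _place_at_min_distance(
    rng: np.random.Generator,
    target_coords: np.ndarray,
    band: tuple[float, float],
    max_tries: int = 2000,
) -> np.ndarray:
    lo, hi = band
    for _ in range(max_tries):
        anchor = target_coords[rng.integers(len(target_coords))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = rng.uniform(lo, hi)
        pos = anchor + r * direction
        dmin = np.min(np.linalg.norm(target_coords - pos, axis=1))
        if lo <= dmin <= hi:
            return pos
    raise RuntimeError(f"could not place water with min distance in {band}")


def plant_waters(
    traj: Trajectory, plans: WaterPlan | Sequence[WaterPlan], seed: int = 0
) -> tuple[Trajectory, GroundTruthManifest]:
    """Append planted water oxygens (residue HOH, atom OH2) to a trajectory.

    The water atom count is fixed across frames (``total`` per plan);
    per frame, exactly ``inside_counts[t]`` of a plan's waters have
    their minimum distance to the plan's target inside the shell, the
    rest strictly outside.  The manifest records the per-frame true
    inside counts.
    """
    if isinstance(plans, WaterPlan):
        plans = [plans]
    rng = np.random.default_rng(seed)
    table = traj.atom_table
    n_frames = traj.n_frames
    resolved = [plan.resolve(n_frames) for plan in plans]
    totals = [total for _, total, _, _ in resolved]
    n_waters = int(sum(totals))
    water_coords = np.zeros((n_frames, n_waters, 3))
    manifest = GroundTruthManifest(seed=seed)
    offset = 0
    for plan, (inside, total, inner, outer) in zip(plans, resolved):
        label = plan.label or plan.target.label or f"plan{offset}"
        for t in range(n_frames):
            tgt = traj.frames[t, plan.target.indices]
            for w in range(total):
                band = inner if w < inside[t] else outer
                water_coords[t, offset + w] = _place_at_min_distance(rng, tgt, band)
        manifest.water_counts[label] = inside.copy()
        offset += total
    next_serial = int(table.serial.max()) + 1 if len(table) else 1
    next_res = int(table.res_seq.max()) + 1 if len(table) else 1
    new_table = Structure(
        serial=np.concatenate([table.serial, np.arange(next_serial, next_serial + n_waters)]),
        name=np.concatenate([table.name, np.full(n_waters, "OH2", dtype="U6")]),
        element=np.concatenate([table.element, np.full(n_waters, "O", dtype="U2")]),
        res_name=np.concatenate([table.res_name, np.full(n_waters, "HOH", dtype="U5")]),
        res_seq=np.concatenate([table.res_seq, np.arange(next_res, next_res + n_waters)]),
        chain=np.concatenate([table.chain, np.full(n_waters, "W", dtype="U4")]),
        is_hetero=np.concatenate([table.is_hetero, np.ones(n_waters, dtype=bool)]),
        coords=np.vstack([table.coords, water_coords[0]]),
        box=table.box,
        source_id=table.source_id,
        seqres=dict(table.seqres),
    )
    frames = np.concatenate([traj.frames, water_coords], axis=1)
    return Trajectory(atom_table=new_table, frames=frames), manifest


def make_peroxidase_model(
    sequence: str,
    disulfides: Sequence[tuple[int, int]] = (),
    proximal_his: int | None = None,
    n_calcium: int = 0,
    with_heme: bool = False,
    source_id: str = "synthetic_peroxidase_model",
    chain: str = "A",
) -> Structure:
    """Schematic synthetic stand-in for a peroxidase crystal structure.

    The sequence is threaded onto an ideal helix; every cysteine gets an
    SG atom, with the SG atoms of each requested disulfide pair placed
    2.03 A apart; every histidine gets an NE2 atom; when ``with_heme``
    a minimal heme (Fe + four pyrrole-like N and four C atoms) is placed
    so that the Fe sits 2.1 A from the NE2 of ``proximal_his``; calcium
    ions are monoatomic hetero residues placed away from the protein.

    The geometry is schematic, not physical — this object is a labelled
    synthetic fixture for the feature detectors, not a model of the real
    crystal structures.
    """
    n = len(sequence)
    helix = make_helix(n, sequence=sequence, chain=chain)
    z_top = float(helix.coords[:, 2].max())

    def ca_of(res: int) -> np.ndarray:
        return helix.coords[(helix.res_seq == res) & (helix.name == "CA")][0]

    # SG positions: paired cysteines bond at 2.03 A on well-separated radial spokes
    sg_pos: dict[int, np.ndarray] = {}
    for k, (r1, r2) in enumerate(disulfides):
        for r in (r1, r2):
            if sequence[r - 1] != "C":
                raise ValueError(f"residue {r} is {sequence[r-1]}, not Cys")
        phi = 2 * np.pi * k / max(len(disulfides), 1)
        z_mid = 0.5 * (ca_of(r1)[2] + ca_of(r2)[2])
        base = np.array([9.0 * np.cos(phi), 9.0 * np.sin(phi), z_mid])
        sg_pos[r1] = base
        sg_pos[r2] = base + np.array([0.0, 0.0, 2.03])
    free_count = 0
    for i, aa in enumerate(sequence):
        res = i + 1
        if aa == "C" and res not in sg_pos:
            phi = np.pi / 7 + 2 * np.pi * (free_count + 0.5) / 11
            sg_pos[res] = np.array([14.0 * np.cos(phi), 14.0 * np.sin(phi), ca_of(res)[2]])
            free_count += 1

    # NE2 on every histidine, pointing radially outward from the helix axis
    ne2_of: dict[int, np.ndarray] = {}
    for i, aa in enumerate(sequence):
        if aa != "H":
            continue
        res = i + 1
        ca = ca_of(res)
        outward = ca.copy()
        outward[2] = 0.0
        outward /= max(np.linalg.norm(outward), 1e-9)
        ne2_of[res] = ca + 1.5 * outward

    names: list[str] = []
    elements: list[str] = []
    res_names: list[str] = []
    res_seqs: list[int] = []
    chains: list[str] = []
    hetero: list[bool] = []
    coords: list[np.ndarray] = []

    def add_atom(name, element, res_name, res_seq, pos, het=False, ch=chain):
        names.append(name)
        elements.append(element)
        res_names.append(res_name)
        res_seqs.append(res_seq)
        chains.append(ch)
        hetero.append(het)
        coords.append(np.asarray(pos, dtype=float))

    # polymer: residues contiguous, side-chain markers inline with their residue
    for i in range(n):
        res = i + 1
        res3 = str(helix.res_name[4 * i])
        for k, atom_name in enumerate(("N", "CA", "C", "O")):
            add_atom(atom_name, atom_name[0], res3, res, helix.coords[4 * i + k])
        if res in sg_pos:
            add_atom("SG", "S", res3, res, sg_pos[res])
        if res in ne2_of:
            add_atom("NE2", "N", res3, res, ne2_of[res])

    het_res = n
    if with_heme:
        if proximal_his is None or proximal_his not in ne2_of:
            raise ValueError("with_heme requires proximal_his pointing at a His residue")
        ne2 = ne2_of[proximal_his]
        ca = ca_of(proximal_his)
        outward = ne2 - ca
        outward /= np.linalg.norm(outward)
        fe = ne2 + 2.1 * outward
        het_res += 1
        add_atom("FE", "Fe", "HEM", het_res, fe, het=True)
        # minimal porphyrin-like cage in the plane normal to the Fe-NE2 axis
        perp1 = np.cross(outward, [0.0, 0.0, 1.0])
        perp1 /= max(np.linalg.norm(perp1), 1e-9)
        perp2 = np.cross(outward, perp1)
        for j, (nm, el, r) in enumerate(
            [("NA", "N", 2.0), ("NB", "N", 2.0), ("NC", "N", 2.0), ("ND", "N", 2.0),
             ("C1A", "C", 3.4), ("C1B", "C", 3.4), ("C1C", "C", 3.4), ("C1D", "C", 3.4)]
        ):
            ang = np.pi / 2 * (j % 4) + (np.pi / 4 if j >= 4 else 0.0)
            add_atom(nm, el, "HEM", het_res, fe + r * (np.cos(ang) * perp1 + np.sin(ang) * perp2), het=True)

    for k in range(n_calcium):
        het_res += 1
        add_atom("CA", "Ca", "CA", het_res, np.array([0.0, 0.0, z_top + 8.0 + 4.0 * k]), het=True)

    m = len(names)
    return Structure(
        serial=np.arange(1, m + 1),
        name=np.array(names, dtype="U6"),
        element=np.array(elements, dtype="U2"),
        res_name=np.array(res_names, dtype="U5"),
        res_seq=np.array(res_seqs, dtype=int),
        chain=np.array(chains, dtype="U4"),
        is_hetero=np.array(hetero, dtype=bool),
        coords=np.asarray(coords, dtype=float),
        source_id=source_id,
    )
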