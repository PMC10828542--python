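"""Structure and trajectory I/O.

Reads fixed-column PDB files (including multi-MODEL files, which become
trajectories), a plain per-frame XYZ text format for trajectories, and
exposes atom selection and sequence extraction.  All coordinates are in
Angstrom.  Residue numbering is always taken verbatim from the source
file: downstream analyses (sequon positions, catalytic residues,
disulfide pairs) are reported in that numbering and renumbering would
silently shift every site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as _struc
import biotite.structure.io.pdb as _pdb
from Bio.SeqUtils import seq1 as _seq1

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSelection",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "read_frames_xyz",
    "write_frames_xyz",
    "load_trajectory",
    "select",
    "select_calpha",
    "select_backbone",
    "select_water_oxygens",
    "select_heme",
    "select_fe",
    "extract_sequence",
    "write_fasta",
    "read_fasta",
]

WATER_RES_NAMES = {"HOH", "SOL", "TIP3", "WAT"}
WATER_O_NAMES = {"O", "OH2", "OW"}
HEME_RES_NAMES = {"HEM", "HEC"}
BACKBONE_NAMES = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised when a PDB or XYZ file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    """One atom record; ``coord`` is a length-3 array in Angstrom."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    coord: np.ndarray
    is_hetero: bool = False


@dataclass
class Structure:
    """An ordered atom table with coordinates.

    Fields are parallel numpy arrays (one entry per atom); ``atom(i)``
    returns an :class:`Atom` view.  ``seqres`` maps chain id to the
    SEQRES residue list (3-letter codes) when the source file had one.
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_seq: np.ndarray
    chain: np.ndarray
    is_hetero: np.ndarray
    coords: np.ndarray
    box: np.ndarray | None = None
    source_id: str = ""
    seqres: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self)

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            element=str(self.element[i]),
            res_name=str(self.res_name[i]),
            res_seq=int(self.res_seq[i]),
            chain=str(self.chain[i]),
            coord=self.coords[i].copy(),
            is_hetero=bool(self.is_hetero[i]),
        )

    def __iter__(self) -> Iterator[Atom]:
        return (self.atom(i) for i in range(len(self)))

    def subset(self, indices: Sequence[int] | np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            serial=self.serial[idx],
            name=self.name[idx],
            element=self.element[idx],
            res_name=self.res_name[idx],
            res_seq=self.res_seq[idx],
            chain=self.chain[idx],
            is_hetero=self.is_hetero[idx],
            coords=self.coords[idx],
            box=None if self.box is None else self.box.copy(),
            source_id=self.source_id,
            seqres=dict(self.seqres),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.subset(np.arange(len(self)))
        out.coords = np.asarray(coords, dtype=float)
        return out

    def residue_groups(self, indices: np.ndarray | None = None) -> list[tuple[tuple[str, int], np.ndarray]]:
        """Group atom indices by (chain, res_seq), preserving file order."""
        if indices is None:
            indices = np.arange(len(self))
        groups: dict[tuple[str, int], list[int]] = {}
        order: list[tuple[str, int]] = []
        for i in np.asarray(indices, dtype=int):
            key = (str(self.chain[i]), int(self.res_seq[i]))
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(int(i))
        return [(key, np.asarray(groups[key], dtype=int)) for key in order]


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom table."""

    atom_table: Structure
    frames: np.ndarray
    times: np.ndarray | None = None
    box_per_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be an (n_frames, n_atoms, 3) array")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != len(self.atom_table):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {len(self.atom_table)}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame(self, t: int) -> Structure:
        return self.atom_table.with_coords(self.frames[t])

    def with_frames(self, frames: np.ndarray) -> "Trajectory":
        return Trajectory(
            atom_table=self.atom_table,
            frames=np.asarray(frames, dtype=float),
            times=None if self.times is None else self.times.copy(),
            box_per_frame=None
            if self.box_per_frame is None
            else self.box_per_frame.copy(),
        )


@dataclass(frozen=True)
class AtomSelection:
    """Sorted unique atom indices into an atom table."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_THREE_TO_ONE_EXTRA = {"MSE": "X"}


def _prevalidate_pdb_lines(lines: list[str]) -> None:
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldstr = line[lo:hi].strip()
                try:
                    float(fieldstr)
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field {fieldstr!r} on line {lineno}"
                    ) from None


def _parse_seqres(lines: list[str]) -> dict[str, list[str]]:
    seqres: dict[str, list[str]] = {}
    for line in lines:
        if line.startswith("SEQRES"):
            chain = line[11].strip() or "A"
            codes = line[19:].split()
            seqres.setdefault(chain, []).extend(codes)
    return seqres


def _normalise_element(el: str, atom_name: str) -> str:
    el = el.strip()
    if not el:
        # infer from atom name: strip digits, common PDB convention
        stripped = "".join(c for c in atom_name if c.isalpha())
        el = stripped[:2] if stripped[:2].upper() in ("FE", "CA", "MG", "ZN", "CL", "NA", "MN", "CU") else stripped[:1]
    return el.capitalize()


def _structure_from_atom_array(
    arr: "_struc.AtomArray", source_id: str, seqres: dict[str, list[str]]
) -> Structure:
    serial = (
        arr.atom_id
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    elements = np.array(
        [_normalise_element(e, n) for e, n in zip(arr.element, arr.atom_name)],
        dtype="U2",
    )
    return Structure(
        serial=np.asarray(serial, dtype=int),
        name=np.asarray(arr.atom_name, dtype="U6"),
        element=elements,
        res_name=np.asarray(arr.res_name, dtype="U5"),
        res_seq=np.asarray(arr.res_id, dtype=int),
        chain=np.asarray(arr.chain_id, dtype="U4"),
        is_hetero=np.asarray(arr.hetero, dtype=bool),
        coords=np.asarray(arr.coord, dtype=float),
        source_id=source_id,
        seqres=seqres,
    )


def read_pdb(path: str | Path) -> Structure | Trajectory:
    """Read a PDB file.

    A single-model file yields a :class:`Structure`; a multi-MODEL file
    yields a :class:`Trajectory` whose atom table comes from the first
    model.  Only blank or 'A' altloc records are kept.  A missing element
    column is tolerated (the element is inferred from the atom name).

    Raises
    ------
    PDBParseError
        On a malformed coordinate field (the offending line is named) or
        on inconsistent atom counts across models.
    """
    path = Path(path)
    pdb_file = _pdb.PDBFile.read(str(path))
    _prevalidate_pdb_lines(pdb_file.lines)
    seqres = _parse_seqres(pdb_file.lines)
    source_id = path.stem
    n_models = pdb_file.get_model_count()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # element guessing
        try:
            if n_models == 1:
                arr = pdb_file.get_structure(
                    model=1, altloc="first", extra_fields=["atom_id"]
                )
                return _structure_from_atom_array(arr, source_id, seqres)
            stack = pdb_file.get_structure(
                model=None, altloc="first", extra_fields=["atom_id"]
            )
        except Exception as exc:  # biotite raises on count mismatch
            raise PDBParseError(
                f"inconsistent atom records across MODEL blocks in {path.name}: {exc}"
            ) from exc
    first = stack[0]
    topology = _structure_from_atom_array(first, source_id, seqres)
    return Trajectory(atom_table=topology, frames=np.asarray(stack.coord, dtype=float))


def _atom_array_from_structure(structure: Structure) -> "_struc.AtomArray":
    n = len(structure)
    arr = _struc.AtomArray(n)
    arr.coord = np.asarray(structure.coords, dtype=np.float32)
    arr.chain_id = structure.chain.astype("U4")
    arr.res_id = structure.res_seq.astype(int)
    arr.res_name = structure.res_name.astype("U5")
    arr.atom_name = structure.name.astype("U6")
    arr.element = np.char.upper(structure.element.astype("U2"))
    arr.hetero = structure.is_hetero.astype(bool)
    arr.set_annotation("atom_id", structure.serial.astype(int))
    return arr


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a Structure (single model) or Trajectory (multi-MODEL) PDB."""
    pdb_file = _pdb.PDBFile()
    if isinstance(obj, Trajectory):
        arrays = [_atom_array_from_structure(obj.frame(t)) for t in range(obj.n_frames)]
        stack = _struc.stack(arrays)
        pdb_file.set_structure(stack)
    else:
        pdb_file.set_structure(_atom_array_from_structure(obj))
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Plain-text per-frame XYZ trajectory format
# ---------------------------------------------------------------------------

def read_frames_xyz(topology: Structure, path: str | Path) -> Trajectory:
    """Read the plain per-frame XYZ text format.

    Each frame is ``n_atoms`` whitespace-separated ``x y z`` rows in
    Angstrom; frames are concatenated.  Lines starting with ``#`` and
    blank lines are ignored.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 3:
                raise PDBParseError(
                    f"expected 3 coordinate columns on line {lineno}, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise PDBParseError(
                    f"malformed coordinate on line {lineno}: {stripped!r}"
                ) from None
    if not rows:
        raise PDBParseError(f"no frames in {path}")
    n_atoms = len(topology)
    if len(rows) % n_atoms != 0:
        frame_index = len(rows) // n_atoms
        raise PDBParseError(
            f"row count {len(rows)} is not a multiple of the topology atom "
            f"count {n_atoms} (incomplete frame {frame_index})"
        )
    frames = np.asarray(rows, dtype=float).reshape(-1, n_atoms, 3)
    return Trajectory(atom_table=topology, frames=frames)


def write_frames_xyz(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# frames={traj.n_frames} atoms={traj.n_atoms} (x y z per atom, A)\n")
        for t in range(traj.n_frames):
            fh.write(f"# frame {t}\n")
            for x, y, z in traj.frames[t]:
                fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")


def load_trajectory(topology_path: str | Path, traj_path: str | Path | None = None) -> Trajectory:
    """Load a trajectory from a multi-model PDB, or topology PDB + XYZ file."""
    obj = read_pdb(topology_path)
    if traj_path is None:
        if isinstance(obj, Trajectory):
            return obj
        return Trajectory(atom_table=obj, frames=obj.coords[None, :, :])
    topology = obj.atom_table if isinstance(obj, Trajectory) else obj
    return read_frames_xyz(topology, traj_path)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _table(obj: Structure | Trajectory) -> Structure:
    return obj.atom_table if isinstance(obj, Trajectory) else obj


def select(
    obj: Structure | Trajectory,
    *,
    names: Sequence[str] | None = None,
    res_names: Sequence[str] | None = None,
    res_seqs: Sequence[int] | None = None,
    chain: str | None = None,
    element: str | None = None,
    hetero: bool | None = None,
    label: str = "",
) -> AtomSelection:
    """Select atoms matching all given (conjunctive) criteria.

    An empty selection is returned, not an error; downstream operations
    decide whether emptiness is acceptable.
    """
    table = _table(obj)
    mask = np.ones(len(table), dtype=bool)
    if names is not None:
        mask &= np.isin(table.name, np.asarray(list(names), dtype="U6"))
    if res_names is not None:
        mask &= np.isin(table.res_name, np.asarray(list(res_names), dtype="U5"))
    if res_seqs is not None:
        mask &= np.isin(table.res_seq, np.asarray(list(res_seqs), dtype=int))
    if chain is not None:
        mask &= table.chain == chain
    if element is not None:
        mask &= np.char.upper(table.element) == element.upper()
    if hetero is not None:
        mask &= table.is_hetero == hetero
    return AtomSelection(indices=np.nonzero(mask)[0], label=label)


def select_calpha(obj: Structure | Trajectory, chain: str | None = None) -> AtomSelection:
    """Polymer (non-hetero) C-alpha atoms."""
    return select(obj, names=["CA"], hetero=False, chain=chain, label="calpha")


def select_backbone(obj: Structure | Trajectory, chain: str | None = None) -> AtomSelection:
    return select(obj, names=list(BACKBONE_NAMES), hetero=False, chain=chain, label="backbone")


def select_water_oxygens(obj: Structure | Trajectory) -> AtomSelection:
    return select(
        obj,
        res_names=sorted(WATER_RES_NAMES),
        names=sorted(WATER_O_NAMES),
        label="water_oxygens",
    )


def select_heme(obj: Structure | Trajectory) -> AtomSelection:
    return select(obj, res_names=sorted(HEME_RES_NAMES), label="heme")


def select_fe(obj: Structure | Trajectory) -> AtomSelection:
    """The heme iron: element Fe within a heme residue."""
    table = _table(obj)
    heme = select(obj, res_names=sorted(HEME_RES_NAMES)).indices
    fe = heme[np.char.upper(table.element[heme]) == "FE"]
    return AtomSelection(indices=fe, label="heme_fe")


# ---------------------------------------------------------------------------
# Sequence extraction, FASTA
# ---------------------------------------------------------------------------

def _three_to_one(code: str) -> str:
    code = code.upper()
    if code in _THREE_TO_ONE_EXTRA:
        return _THREE_TO_ONE_EXTRA[code]
    one = _seq1(code.capitalize(), undef_code="X")
    return one if one.isalpha() and one.isupper() else "X"


def extract_sequence(
    structure: Structure, chain: str, use_seqres: bool = True
) -> tuple[str, list[int]]:
    """One-letter sequence of a chain plus residue-number map.

    Prefers SEQRES when present (``use_seqres=True``), otherwise derives
    the sequence from the polymer ATOM records.  Nonstandard residues map
    to ``'X'`` with a warning.  Returns ``(sequence, numbering)`` where
    ``numbering[i]`` is the residue number of sequence position ``i``.
    """
    chains = set(str(c) for c in structure.chain) | set(structure.seqres)
    if chain not in chains:
        raise KeyError(f"unknown chain {chain!r}; available: {sorted(chains)}")
    polymer_idx = np.nonzero((structure.chain == chain) & ~structure.is_hetero)[0]
    first_res = int(structure.res_seq[polymer_idx[0]]) if len(polymer_idx) else 1
    if use_seqres and chain in structure.seqres:
        codes = structure.seqres[chain]
        seq = "".join(_three_to_one(c) for c in codes)
        numbering = list(range(first_res, first_res + len(codes)))
    else:
        seen: list[tuple[int, str]] = []
        for i in polymer_idx:
            key = (int(structure.res_seq[i]), str(structure.res_name[i]))
            if not seen or seen[-1][0] != key[0]:
                seen.append(key)
        seq = "".join(_three_to_one(code) for _, code in seen)
        numbering = [num for num, _ in seen]
    if "X" in seq:
        warnings.warn("nonstandard residue(s) mapped to 'X'", stacklevel=2)
    return seq, numbering


def write_fasta(sequence: str, identifier: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{identifier}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read the first record of a FASTA file; returns (identifier, sequence)."""
    identifier = ""
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if chunks:
                    break
                identifier = line[1:].split()[0] if len(line) > 1 else ""
            elif line:
                chunks.append(line)
    if not chunks:
        raise ValueError(f"no sequence in {path}")
    return identifier, "".join(chunks).upper()
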