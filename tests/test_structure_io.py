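import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import splitperox as sp
from splitperox.structure_io import (
    PDBParseError,
    read_fasta,
    read_frames_xyz,
    write_fasta,
    write_frames_xyz,
)

SINGLE_ATOM = (
    "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
)

TRIPEPTIDE = """\
SEQRES   1 A    3  ALA GLY SER
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
HETATM    5 FE   HEM A   9       5.000   0.000   2.000  1.00  0.00          FE
HETATM    6  OH2 HOH A  10       8.000   0.000   2.000  1.00  0.00           O
END
"""


def _multi_model(z_values):
    blocks = []
    for k, z in enumerate(z_values, start=1):
        blocks.append(f"MODEL     {k:4d}\n")
        blocks.append(
            f"ATOM      1  CA  ALA A   1       0.000   0.000{z:8.3f}  1.00  0.00           C\n"
        )
        blocks.append(
            f"ATOM      2  CA  GLY A   2       3.800   0.000{z:8.3f}  1.00  0.00           C\n"
        )
        blocks.append("ENDMDL\n")
    return "".join(blocks) + "END\n"


def test_single_atom_record_fields(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(SINGLE_ATOM)
    structure = sp.read_pdb(path)
    assert isinstance(structure, sp.Structure)
    assert len(structure) == 1
    atom = structure.atom(0)
    assert atom.name == "CA" and atom.res_name == "ALA"
    assert atom.res_seq == 1 and atom.chain == "A"
    np.testing.assert_allclose(atom.coord, [0.0, 0.0, 0.0])


def test_multi_model_becomes_trajectory_and_matches_per_model_reads(tmp_path):
    z = [0.0, 1.5, -2.25]
    path = tmp_path / "traj.pdb"
    path.write_text(_multi_model(z))
    traj = sp.read_pdb(path)
    assert isinstance(traj, sp.Trajectory)
    assert traj.n_frames == 3
    for k, zk in enumerate(z):
        single = tmp_path / f"model{k}.pdb"
        single.write_text(_multi_model([zk]).replace("MODEL", "XODEL").replace("ENDMDL", "XNDMDL"))
        frame_struct = sp.read_pdb(single)
        np.testing.assert_allclose(traj.frames[k], frame_struct.coords, atol=1e-6)


def test_identical_models_give_identical_frames(tmp_path):
    path = tmp_path / "traj.pdb"
    path.write_text(_multi_model([1.0, 1.0, 1.0]))
    traj = sp.read_pdb(path)
    assert traj.n_frames == 3
    assert np.all(traj.frames[0] == traj.frames[1])
    assert np.all(traj.frames[1] == traj.frames[2])


def test_malformed_coordinate_names_line(tmp_path):
    bad = SINGLE_ATOM.replace("   0.000   0.000   0.000", "   0.000   xx.000   0.000")
    path = tmp_path / "bad.pdb"
    path.write_text("REMARK\n" + bad)
    with pytest.raises(PDBParseError, match="line 2"):
        sp.read_pdb(path)


def test_inconsistent_model_atom_counts_error(tmp_path):
    text = _multi_model([0.0, 1.0])
    # drop one atom from the second model
    lines = [ln for ln in text.splitlines(keepends=True)]
    del lines[-4]
    path = tmp_path / "bad.pdb"
    path.write_text("".join(lines))
    with pytest.raises(PDBParseError, match="MODEL"):
        sp.read_pdb(path)


def test_pdb_roundtrip_preserves_atoms(tmp_path, synthetic_hrp_model):
    path = tmp_path / "model.pdb"
    sp.write_pdb(synthetic_hrp_model, path)
    back = sp.read_pdb(path)
    assert len(back) == len(synthetic_hrp_model)
    assert list(back.name) == list(synthetic_hrp_model.name)
    assert list(back.res_seq) == list(synthetic_hrp_model.res_seq)
    assert list(back.is_hetero) == list(synthetic_hrp_model.is_hetero)
    np.testing.assert_allclose(back.coords, synthetic_hrp_model.coords, atol=1.5e-3)


def test_trajectory_pdb_roundtrip(tmp_path, helix20):
    traj, _ = sp.make_trajectory(helix20, sp.SyntheticSpec(n_frames=3, sigma=0.3, seed=7))
    path = tmp_path / "traj.pdb"
    sp.write_pdb(traj, path)
    back = sp.read_pdb(path)
    assert isinstance(back, sp.Trajectory)
    np.testing.assert_allclose(back.frames, traj.frames, atol=1.5e-3)


class TestSelect:
    def test_calpha_on_tripeptide(self, tmp_path):
        path = tmp_path / "tri.pdb"
        path.write_text(TRIPEPTIDE)
        structure = sp.read_pdb(path)
        assert len(sp.select(structure, names=["CA"], hetero=False)) == 3
        assert len(sp.select_calpha(structure)) == 3

    def test_water_oxygens_and_heme(self, tmp_path):
        path = tmp_path / "tri.pdb"
        path.write_text(TRIPEPTIDE)
        structure = sp.read_pdb(path)
        assert len(sp.select_water_oxygens(structure)) == 1
        assert len(sp.select_heme(structure)) == 1
        fe = sp.select_fe(structure)
        assert len(fe) == 1
        assert structure.atom(fe.indices[0]).element.upper() == "FE"

    def test_conjunctive_predicates_and_empty_ok(self, synthetic_hrp_model):
        sel = sp.select(synthetic_hrp_model, names=["CA"], res_seqs=[170], hetero=False)
        assert len(sel) == 1
        empty = sp.select(synthetic_hrp_model, names=["ZZ9"])
        assert len(empty) == 0

    def test_select_idempotent_and_sorted(self, synthetic_hrp_model):
        a = sp.select(synthetic_hrp_model, names=["CA"], hetero=False)
        b = sp.select(synthetic_hrp_model, hetero=False, names=["CA"])
        assert np.array_equal(a.indices, b.indices)
        assert np.all(np.diff(a.indices) > 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["CA", "N", "C", "O", "SG"]), min_size=1, max_size=3))
    def test_selection_indices_within_range(self, names):
        structure = sp.make_helix(8)
        sel = sp.select(structure, names=names)
        assert np.all((sel.indices >= 0) & (sel.indices < len(structure)))
        assert len(np.unique(sel.indices)) == len(sel.indices)


class TestSequenceExtraction:
    def test_seqres_preferred(self, tmp_path):
        path = tmp_path / "tri.pdb"
        path.write_text(TRIPEPTIDE)
        structure = sp.read_pdb(path)
        seq, numbering = sp.extract_sequence(structure, "A")
        assert seq == "AGS"
        assert numbering == [1, 2, 3]

    def test_atom_derived_when_no_seqres(self, synthetic_hrp_model, hrp_sequence):
        seq, numbering = sp.extract_sequence(synthetic_hrp_model, "A")
        assert seq == hrp_sequence
        assert numbering[0] == 1 and numbering[-1] == 308

    def test_mse_maps_to_x_with_warning(self, tmp_path):
        text = TRIPEPTIDE.replace("SEQRES   1 A    3  ALA GLY SER",
                                  "SEQRES   1 A    3  ALA MSE SER")
        path = tmp_path / "mse.pdb"
        path.write_text(text)
        structure = sp.read_pdb(path)
        with pytest.warns(UserWarning, match="nonstandard"):
            seq, _ = sp.extract_sequence(structure, "A")
        assert seq == "AXS"

    def test_unknown_chain_raises(self, synthetic_hrp_model):
        with pytest.raises(KeyError, match="unknown chain"):
            sp.extract_sequence(synthetic_hrp_model, "Q")


class TestFramesXYZ:
    def test_roundtrip_to_format_precision(self, tmp_path, helix20):
        traj, _ = sp.make_trajectory(helix20, sp.SyntheticSpec(n_frames=4, sigma=0.4, seed=3))
        path = tmp_path / "frames.xyz"
        write_frames_xyz(traj, path)
        back = read_frames_xyz(helix20, path)
        assert back.n_frames == 4
        np.testing.assert_allclose(back.frames, traj.frames, atol=5.1e-4)

    def test_empty_file_errors(self, tmp_path, helix20):
        path = tmp_path / "empty.xyz"
        path.write_text("# nothing here\n")
        with pytest.raises(PDBParseError, match="no frames"):
            read_frames_xyz(helix20, path)

    def test_count_mismatch_names_frame(self, tmp_path, helix20):
        path = tmp_path / "bad.xyz"
        rows = ["0.0 0.0 0.0"] * (len(helix20) + 3)
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(PDBParseError, match="frame 1"):
            read_frames_xyz(helix20, path)


def test_fasta_roundtrip(tmp_path, hrp_sequence):
    path = tmp_path / "seq.fasta"
    write_fasta(hrp_sequence, "HRP_test", path)
    ident, seq = read_fasta(path)
    assert ident == "HRP_test"
    assert seq == hrp_sequence
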