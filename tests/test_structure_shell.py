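import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ortho_group

from fadtools.structure_shell import (
    Atom,
    StructureModel,
    StructureError,
    find_his_boxes,
    his_box_positions,
    map_model_to_sequence,
    read_structure,
    shell_residues,
    write_structure,
)
from fadtools.synthetic_data import simulate_structure_model


class TestHisBoxes:
    def test_single_hxxxh(self):
        boxes = find_his_boxes("AHAAAHA")
        assert len(boxes) == 1
        assert boxes[0].motif == "HxxxH"
        assert boxes[0].start == 2
        assert boxes[0].his_positions == (2, 6)

    def test_hxxhh_not_double_counted(self):
        boxes = find_his_boxes("HAAHH")
        assert [(b.motif, b.start) for b in boxes] == [("HxxHH", 1)]
        assert boxes[0].his_positions == (1, 4, 5)

    def test_overlapping_occurrences_all_reported(self):
        # HxxxH at 1 and 5 share the His at position 5
        boxes = find_his_boxes("HAAAHAAAH")
        assert [(b.motif, b.start) for b in boxes] == [("HxxxH", 1), ("HxxxH", 5)]

    def test_desaturase_like_arrangement(self):
        # tripartite motif layout: HxxxH ... HxxHH ... lone H ... HxxHH
        seq = (
            "M" * 104 + "HAAAH"          # 105..109
            + "A" * 31 + "HAAHH"          # 141..145
            + "A" * 149 + "H"             # 295
            + "A" * 41 + "HAAHH"          # 337..341
            + "A" * 20
        )
        boxes = find_his_boxes(seq)
        assert [(b.motif, b.start) for b in boxes] == [
            ("HxxxH", 105), ("HxxHH", 141), ("HxxHH", 337)
        ]
        ligands = his_box_positions(boxes, extra=(295,))
        assert len(ligands) == 9  # 2 + 3 + 3 box histidines plus the lone one
        assert 295 in ligands

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_his_boxes("")


class TestReadWriteStructure:
    def test_toy_file_exact_coordinates(self, tmp_path, toy_shell_model):
        layout, model = toy_shell_model
        path = tmp_path / "toy.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert len(back.atoms) == len(model.atoms)
        # PDB coordinates are fixed-width with 3 decimals
        np.testing.assert_allclose(
            back.coordinates, model.coordinates, atol=5e-4
        )

    def test_metal_auto_flagged(self, tmp_path, toy_shell_model):
        _, model = toy_shell_model
        path = tmp_path / "toy.pdb"
        write_structure(model, path)
        back = read_structure(path)
        metals = back.metal_atoms()
        assert [m.element for m in metals] == ["FE"]

    def test_unparseable_file_is_error(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a pdb\n")
        with pytest.raises(StructureError):
            read_structure(bad)


def brute_force_shell(model, radius):
    """Independent all-pairs oracle for shell membership and distances."""
    metals = np.array([[a.x, a.y, a.z] for a in model.metal_atoms()])
    out = {}
    metal_idx = set(model.metal_indices)
    for i, atom in enumerate(model.atoms):
        if i in metal_idx:
            continue
        d = min(
            float(np.sqrt(((np.array([atom.x, atom.y, atom.z]) - m) ** 2).sum()))
            for m in metals
        )
        if d <= radius:
            key = atom.residue_key
            out[key] = min(out.get(key, np.inf), d)
    return out


def random_model(rng, n_atoms=200):
    atoms = [
        Atom("A", 9000 + i, "", "FE", "FE", "FE", *rng.uniform(-8, 8, 3))
        for i in range(rng.integers(1, 3))
    ]
    n_metals = len(atoms)
    for i in range(n_atoms):
        atoms.append(
            Atom(
                chain="A",
                res_number=i // 4 + 1,
                insertion_code="",
                res_name="ALA",
                atom_name=f"C{i % 4}",
                element="C",
                x=float(rng.uniform(-15, 15)),
                y=float(rng.uniform(-15, 15)),
                z=float(rng.uniform(-15, 15)),
            )
        )
    return StructureModel(atoms=atoms, metal_indices=list(range(n_metals)))


class TestShellResidues:
    def test_inside_and_outside(self):
        model = simulate_structure_model([("ALA", 1, 3.0), ("GLY", 2, 6.0)], seed=0)
        shell = shell_residues(model, radius=5.0)
        assert [(r.res_number, r.min_distance) for r in shell] == [(1, 3.0)]

    def test_tight_radius_empty(self, toy_shell_model):
        _, model = toy_shell_model
        assert shell_residues(model, radius=0.5) == []

    def test_boundary_inclusive(self):
        model = simulate_structure_model([("ALA", 1, 5.0)], seed=0)
        assert len(shell_residues(model, radius=5.0)) == 1

    def test_no_metals_is_error(self):
        model = simulate_structure_model([("ALA", 1, 3.0)], seed=0)
        with pytest.raises(StructureError):
            shell_residues(model, radius=5.0, metal_selection=["ZN"])

    def test_ligand_his_flagging(self, toy_shell_model):
        _, model = toy_shell_model
        shell = shell_residues(model, radius=5.0, ligand_his={105, 141})
        flags = {r.res_number: r.is_metal_ligand_his for r in shell}
        assert flags == {105: True, 141: True, 157: False, 290: False, 308: False}
        non_his = [r.res_number for r in shell if not r.is_metal_ligand_his]
        assert sorted(non_his) == [157, 290, 308]

    def test_matches_brute_force_on_random_structures(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            model = random_model(rng)
            radius = float(rng.uniform(2, 12))
            got = {
                (r.chain, r.res_number, r.insertion_code): r.min_distance
                for r in shell_residues(model, radius=radius)
            }
            expected = brute_force_shell(model, radius)
            assert got.keys() == expected.keys()
            for key in got:
                assert abs(got[key] - expected[key]) < 1e-9

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(7)
        model = random_model(rng)
        radii = sorted(rng.uniform(1, 14, size=6))
        previous = set()
        for r in radii:
            current = {s.res_number for s in shell_residues(model, radius=r)}
            assert previous <= current
            previous = current

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(99)
        model = random_model(rng)
        base = {
            r.res_number: r.min_distance for r in shell_residues(model, radius=6.0)
        }
        rotation = ortho_group.rvs(3, random_state=4)
        translation = rng.uniform(-20, 20, 3)
        moved_atoms = []
        for a in model.atoms:
            xyz = rotation @ np.array([a.x, a.y, a.z]) + translation
            moved_atoms.append(
                Atom(a.chain, a.res_number, a.insertion_code, a.res_name,
                     a.atom_name, a.element, *map(float, xyz))
            )
        moved = StructureModel(atoms=moved_atoms, metal_indices=model.metal_indices)
        got = {r.res_number: r.min_distance for r in shell_residues(moved, radius=6.0)}
        assert got.keys() == base.keys()
        for k in got:
            assert abs(got[k] - base[k]) < 1e-6


class TestMapModelToSequence:
    def _model_from_sequence(self, residues, numbering_offset=0):
        three = {"A": "ALA", "H": "HIS", "F": "PHE", "W": "TRP", "L": "LEU",
                 "I": "ILE", "G": "GLY", "S": "SER"}
        atoms = [
            Atom("A", i + 1 + numbering_offset, "", three[aa], "CA", "C",
                 float(i), 0.0, 0.0)
            for i, aa in enumerate(residues)
        ]
        return StructureModel(atoms=atoms, metal_indices=[])

    def test_identity_numbering(self):
        seq = "AHFWLIGS" * 5
        model = self._model_from_sequence(seq)
        nmap = map_model_to_sequence(model, seq)
        assert nmap.offset == 0
        assert nmap.mismatches == ()
        assert nmap.sequence_position(7) == 7

    def test_offset_detected(self):
        seq = "AHFWLIGS" * 5
        model = self._model_from_sequence(seq, numbering_offset=-1)  # 0-based model
        nmap = map_model_to_sequence(model, seq)
        assert nmap.offset == 1
        assert nmap.mismatches == ()

    def test_mismatches_reported_exactly(self):
        seq = "AHFWLIGS" * 25  # 200 residues
        model = self._model_from_sequence(seq)
        atoms = list(model.atoms)
        for idx in (9, 49, 99):  # corrupt 3 residue names
            a = atoms[idx]
            atoms[idx] = Atom(a.chain, a.res_number, a.insertion_code, "GLY",
                              a.atom_name, a.element, a.x, a.y, a.z)
        corrupted = StructureModel(atoms=atoms, metal_indices=[])
        nmap = map_model_to_sequence(corrupted, seq)
        assert sorted(m[0] for m in nmap.mismatches) == [10, 50, 100]

    def test_too_many_mismatches_is_error(self):
        seq = "A" * 50
        model = self._model_from_sequence("HFWLIGSH" * 5 + "AHFWLIGSHF")
        with pytest.raises(StructureError, match="renumber"):
            map_model_to_sequence(model, seq, offset=0)
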