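"""Transition-dipole geometry from coordinates, with rotation-matrix oracles."""

import math

import numpy as np
import pytest

from polir import structure as st
from polir.structure import (
    Atom,
    GroupResolutionError,
    Structure,
    StructureError,
    TdmVector,
    amide_i_tdm,
    angle_table,
    axis_from_vector,
    bond_tdm,
    electronic_axis,
    ideal_helix_structure,
    load_structure,
    relative_angle,
    save_pdb,
)


def make_structure(atom_specs):
    atoms = [
        Atom(serial=i + 1, name=name, resname=res, chain="A", resnum=num, icode="",
             x=float(x), y=float(y), z=float(z))
        for i, (name, res, num, x, y, z) in enumerate(atom_specs)
    ]
    return Structure(atoms)


@pytest.fixture()
def planar_peptide():
    """C at origin, O on +z, N of the next residue in the xz-plane 120 deg away."""
    n_pos = 1.33 * np.array([math.sin(math.radians(120)), 0.0, math.cos(math.radians(120))])
    return make_structure(
        [
            ("CA", "GLY", 1, -1.2, -0.8, 0.0),
            ("C", "GLY", 1, 0.0, 0.0, 0.0),
            ("O", "GLY", 1, 0.0, 0.0, 1.23),
            ("N", "GLY", 2, n_pos[0], n_pos[1], n_pos[2]),
        ]
    )


def rodrigues(v, axis, angle_deg):
    a = np.asarray(axis) / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    return (
        v * math.cos(th)
        + np.cross(a, v) * math.sin(th)
        + a * np.dot(a, v) * (1 - math.cos(th))
    )


class TestBondTdm:
    def test_axis_aligned_bond(self):
        s = make_structure([("CD", "GLU", 1, 0, 0, 0), ("OE2", "GLU", 1, 0, 0, 1.23)])
        tdm = bond_tdm(s, "A", 1, "CD", "OE2")
        np.testing.assert_allclose(tdm.vector, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(tdm.anchor, [0, 0, 0])

    def test_arbitrary_bond_matches_hand_computation(self):
        p, q = np.array([1.0, -2.0, 0.5]), np.array([2.1, -1.2, 1.4])
        s = make_structure([("CD", "GLU", 7, *p), ("OE1", "GLU", 7, *q)])
        tdm = bond_tdm(s, "A", 7, "CD", "OE1")
        np.testing.assert_allclose(tdm.vector, (q - p) / np.linalg.norm(q - p), atol=1e-12)

    def test_coincident_atoms_rejected(self):
        s = make_structure([("C", "GLY", 1, 0, 0, 0), ("O", "GLY", 1, 0, 0, 0)])
        with pytest.raises(StructureError, match="degenerate"):
            bond_tdm(s, "A", 1, "C", "O")

    def test_missing_atom_named_in_error(self):
        s = make_structure([("C", "GLY", 1, 0, 0, 0)])
        with pytest.raises(StructureError, match="OE2"):
            bond_tdm(s, "A", 1, "C", "OE2")


class TestAmideITdm:
    def test_zero_rotation_is_co_direction(self, planar_peptide):
        tdm = amide_i_tdm(planar_peptide, "A", 1, rotation_deg=0.0)
        np.testing.assert_allclose(tdm.vector, [0, 0, 1], atol=1e-12)

    def test_90_rotation_is_in_plane_toward_nitrogen(self, planar_peptide):
        tdm = amide_i_tdm(planar_peptide, "A", 1, rotation_deg=90.0)
        assert abs(tdm.vector[2]) < 1e-12  # orthogonal to C=O
        assert abs(tdm.vector[1]) < 1e-12  # in the xz (NCO) plane
        assert tdm.vector[0] > 0  # positive N-side component

    def test_matches_rodrigues_oracle(self, planar_peptide):
        """Tilt toward N equals rotating e_CO about the NCO-plane normal."""
        c = planar_peptide.atom("A", 1, "C").pos
        o = planar_peptide.atom("A", 1, "O").pos
        n = planar_peptide.atom("A", 2, "N").pos
        e_co = (o - c) / np.linalg.norm(o - c)
        normal = np.cross(e_co, (n - c) / np.linalg.norm(n - c))
        expected = rodrigues(e_co, normal, 10.0)
        tdm = amide_i_tdm(planar_peptide, "A", 1, rotation_deg=10.0)
        np.testing.assert_allclose(tdm.vector, expected, atol=1e-9)

    @pytest.mark.parametrize("theta", [5.0, 10.0, 20.0, 45.0])
    def test_unit_norm_in_plane_exact_angle(self, theta):
        rng = np.random.default_rng(11)
        for _ in range(10):
            c = rng.normal(size=3)
            o = c + rng.normal(size=3)
            n = c + rng.normal(size=3)
            e_co = (o - c) / np.linalg.norm(o - c)
            e_cn = (n - c) / np.linalg.norm(n - c)
            if np.linalg.norm(np.cross(e_co, e_cn)) < 0.1:
                continue
            s = make_structure([("C", "ALA", 1, *c), ("O", "ALA", 1, *o), ("N", "ALA", 2, *n)])
            tdm = amide_i_tdm(s, "A", 1, rotation_deg=theta)
            assert np.linalg.norm(tdm.vector) == pytest.approx(1.0, abs=1e-12)
            # in the NCO plane: no component along the plane normal
            normal = np.cross(e_co, e_cn)
            assert abs(np.dot(tdm.vector, normal / np.linalg.norm(normal))) < 1e-9
            angle_to_co = math.degrees(math.acos(np.clip(np.dot(tdm.vector, e_co), -1, 1)))
            assert angle_to_co == pytest.approx(theta, abs=1e-9)

    def test_collinear_geometry_rejected(self):
        s = make_structure(
            [("C", "ALA", 1, 0, 0, 0), ("O", "ALA", 1, 0, 0, 1.0), ("N", "ALA", 2, 0, 0, 2.0)]
        )
        with pytest.raises(StructureError, match="collinear"):
            amide_i_tdm(s, "A", 1)


class TestRelativeAngle:
    def test_parallel_antiparallel_orthogonal(self):
        v1 = TdmVector(np.array([1.0, 0, 0]), np.zeros(3))
        assert relative_angle(v1, TdmVector(np.array([1.0, 0, 0]), np.zeros(3))) == 0.0
        assert relative_angle(v1, TdmVector(np.array([-1.0, 0, 0]), np.zeros(3))) == 0.0
        assert relative_angle(v1, TdmVector(np.array([0, 1.0, 0]), np.zeros(3))) == pytest.approx(90.0)

    def test_symmetric_and_sign_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            va = TdmVector(a / np.linalg.norm(a), np.zeros(3))
            vb = TdmVector(b / np.linalg.norm(b), np.zeros(3))
            vb_flip = TdmVector(-vb.vector, np.zeros(3))
            assert relative_angle(va, vb) == pytest.approx(relative_angle(vb, va))
            assert relative_angle(va, vb_flip) == pytest.approx(relative_angle(va, vb))
            assert 0.0 <= relative_angle(va, vb) <= 90.0


def test_rigid_transform_invariance():
    """Angles are unchanged by a random global rotation plus translation."""
    helix = ideal_helix_structure(10)
    axis = st.helix_axis(helix)
    angles = [relative_angle(amide_i_tdm(helix, "A", i), axis) for i in range(2, 9)]

    rng = np.random.default_rng(5)
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.normal(scale=30.0, size=3)
    moved = Structure(
        [
            Atom(a.serial, a.name, a.resname, a.chain, a.resnum, a.icode,
                 *(q @ a.pos + shift))
            for a in helix.atoms
        ]
    )
    axis2 = st.helix_axis(moved)
    angles2 = [relative_angle(amide_i_tdm(moved, "A", i), axis2) for i in range(2, 9)]
    np.testing.assert_allclose(angles2, angles, atol=1e-9)


class TestElectronicAxis:
    def test_two_atoms_on_x(self):
        s = make_structure([("C5", "RET", 300, 0, 0, 0), ("C15", "RET", 300, 7.5, 0, 0)])
        axis = electronic_axis(s, "A", 300, "C5", "C15")
        np.testing.assert_allclose(axis.vector, [1, 0, 0], atol=1e-12)
        assert relative_angle(axis, bond_tdm(s, "A", 300, "C5", "C15")) == 0.0

    def test_raw_vector_normalized(self):
        axis = axis_from_vector([0.0, 3.0, 4.0])
        np.testing.assert_allclose(axis.vector, [0.0, 0.6, 0.8], atol=1e-12)
        with pytest.raises(ValueError):
            axis_from_vector([0.0, 0.0, 0.0])


class TestAngleTable:
    def test_empty_groups(self):
        helix = ideal_helix_structure(6)
        table = angle_table(helix, st.helix_axis(helix), [])
        assert len(table) == 0
        assert "angle_deg" in table.columns

    def test_ideal_helix_amide_angles_cluster(self):
        """All peptide planes of an ideal helix share one screw relation,
        so amide I angles to the helix axis must cluster tightly."""
        helix = ideal_helix_structure(14)
        axis = st.helix_axis(helix)
        groups = [
            {"kind": "amide", "chain": "A", "resnum": i, "label": f"res{i}"}
            for i in range(3, 13)
        ]
        table = angle_table(helix, axis, groups)
        assert len(table) == 10
        assert table["angle_deg"].max() - table["angle_deg"].min() < 5.0

    def test_parallel_carbonyls_give_zero(self):
        atoms = []
        for i in range(1, 4):
            atoms += [
                ("C", "GLY", i, 0.0, 0.0, float(i) * 3),
                ("O", "GLY", i, 0.0, 0.0, float(i) * 3 + 1.23),
            ]
        s = make_structure(atoms)
        axis = axis_from_vector([0.0, 0.0, 1.0])
        groups = [
            {"kind": "bond", "chain": "A", "resnum": i, "atom_from": "C", "atom_to": "O"}
            for i in range(1, 4)
        ]
        table = angle_table(s, axis, groups)
        np.testing.assert_allclose(table["angle_deg"], 0.0, atol=1e-9)

    def test_failures_collected(self):
        helix = ideal_helix_structure(6)
        groups = [
            {"kind": "amide", "chain": "A", "resnum": 3},
            {"kind": "amide", "chain": "B", "resnum": 3, "label": "wrong chain"},
            {"kind": "bond", "chain": "A", "resnum": 2, "atom_from": "C", "atom_to": "XX"},
        ]
        with pytest.raises(GroupResolutionError) as err:
            angle_table(helix, st.helix_axis(helix), groups)
        assert len(err.value.failures) == 2


class TestPdbIO:
    def test_minimal_file(self, tmp_path, planar_peptide):
        path = tmp_path / "pep.pdb"
        save_pdb(planar_peptide, path)
        loaded = load_structure(path)
        assert len(loaded.atoms) == 4
        np.testing.assert_allclose(
            loaded.atom("A", 1, "O").pos, planar_peptide.atom("A", 1, "O").pos, atol=1e-3
        )

    def test_first_model_only(self, tmp_path):
        path = tmp_path / "multi.pdb"
        path.write_text(
            "MODEL        1\n"
            "ATOM      1  C   GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  C   GLY A   1       9.000   9.000   9.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        loaded = load_structure(path)
        assert len(loaded.atoms) == 1
        np.testing.assert_allclose(loaded.atom("A", 1, "C").pos, [0, 0, 0])

    def test_altloc_tie_keeps_first(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  C  AGLY A   1       0.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  C  BGLY A   1       5.000   5.000   5.000  0.50  0.00           C\n"
            "END\n"
        )
        loaded = load_structure(path)
        assert len(loaded.atoms) == 1
        np.testing.assert_allclose(loaded.atom("A", 1, "C").pos, [0, 0, 0])

    def test_missing_file_and_empty_file(self, tmp_path):
        with pytest.raises(StructureError):
            load_structure(tmp_path / "absent.pdb")
        empty = tmp_path / "empty.pdb"
        empty.write_text("END\n")
        with pytest.raises(StructureError):
            load_structure(empty)
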