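"""Geometry measurements: superposition, docking angle, dihedrals, contacts,
angles, and Lee-Richards SASA (with independent oracles)."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tightbind.interface_geometry import (
    CHOTHIA_RADII,
    ContactThresholds,
    GeometryError,
    angles_at_center,
    atom_distance,
    buried_area,
    chi1,
    contacts,
    dihedral,
    docking_angle,
    rotation_angle,
    sasa,
    superpose,
)
from tightbind.structure_io import SelectionError, StructureModel
from conftest import chain_of_cas, make_atom


def rigid(model: StructureModel, seed: int = 0) -> StructureModel:
    """Random rigid motion of a model (rotation + translation)."""
    rng = np.random.default_rng(seed)
    r = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return model.with_coords(model.coords @ r.T + t)


class TestSuperposition:
    def test_identity_on_identical_sets(self):
        x = np.random.default_rng(0).normal(size=(12, 3))
        sup = superpose(x, x)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self):
        x = np.random.default_rng(1).normal(size=(10, 3))
        rz = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        sup = superpose(x, x @ rz.T + [1.0, 2.0, 3.0])
        assert rotation_angle(sup) == pytest.approx(30.0, abs=1e-9)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(2)
        sup = superpose(rng.normal(size=(8, 3)), rng.normal(size=(8, 3)))
        r = sup.rotation
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-8)

    def test_applying_transform_then_resuperposing_is_identity(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(9, 3)), rng.normal(size=(9, 3))
        sup = superpose(x, y)
        again = superpose(sup.apply(x), y)
        assert rotation_angle(again) == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_sets_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            superpose(line, line)
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rotation_angle_closed_forms(self):
        assert rotation_angle(np.eye(3)) == pytest.approx(0.0)
        flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
        assert rotation_angle(flip) == pytest.approx(180.0)
        ten = Rotation.from_euler("y", 10, degrees=True).as_matrix()
        assert rotation_angle(ten @ ten) == pytest.approx(20.0, abs=1e-9)


class TestDockingAngle:
    def test_self_comparison_is_zero(self, toy_complex_pair):
        c1, _ = toy_complex_pair
        assert docking_angle(c1, c1, "E", "I") == pytest.approx(0.0, abs=1e-9)

    def test_constructed_eight_degree_rotation(self, toy_complex_pair):
        c1, c2 = toy_complex_pair
        assert docking_angle(c1, c2, "E", "I") == pytest.approx(8.0, abs=1e-6)

    def test_symmetric_in_argument_order(self, toy_complex_pair):
        c1, c2 = toy_complex_pair
        assert docking_angle(c1, c2, "E", "I") == pytest.approx(
            docking_angle(c2, c1, "E", "I"), abs=1e-6)

    def test_missing_chain_reported(self, toy_complex_pair):
        c1, c2 = toy_complex_pair
        with pytest.raises(SelectionError):
            docking_angle(c1, c2, "X", "I")


class TestDihedrals:
    def test_trans_cis_and_gauche_constructions(self):
        # N at +x of CA, axis along +y: gamma's perpendicular component at
        # -x is anti (180), at +x eclipsed (0), rotated -60 gives gauche-.
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 2, 0)) == pytest.approx(180.0)
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 2, 0)) == pytest.approx(0.0)
        g_minus = (0.5, 2.0, math.sin(math.radians(60)))
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), g_minus) == pytest.approx(-60.0)

    def test_chi1_of_constructed_serine(self):
        atoms = [
            make_atom("N", "N", 1.0, 0.0, 0.0, resnum=741, resname="SER"),
            make_atom("CA", "C", 0.0, 0.0, 0.0, resnum=741, resname="SER"),
            make_atom("CB", "C", 0.0, 1.5, 0.0, resnum=741, resname="SER"),
            make_atom("OG", "O", -1.0, 2.5, 0.0, resnum=741, resname="SER"),
        ]
        measure = chi1(StructureModel(atoms), "A:741")
        assert measure.degrees == pytest.approx(180.0)
        assert measure.resname == "SER"

    def test_chi1_reflection_negates(self):
        atoms = [
            make_atom("N", "N", 1.0, 0.2, 0.3, resnum=1, resname="HIS"),
            make_atom("CA", "C", 0.0, 0.0, 0.0, resnum=1, resname="HIS"),
            make_atom("CB", "C", 0.1, 1.5, 0.2, resnum=1, resname="HIS"),
            make_atom("CG", "C", 1.0, 2.4, -0.5, resnum=1, resname="HIS"),
        ]
        model = StructureModel(atoms)
        mirrored = model.with_coords(model.coords * [1.0, 1.0, -1.0])
        assert chi1(mirrored, "A:1").degrees == pytest.approx(
            -chi1(model, "A:1").degrees)

    def test_chi1_cross_checked_against_biotite(self):
        import biotite.structure as struc

        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * 3
            ours = dihedral(*pts)
            theirs = math.degrees(struc.dihedral(*(p.astype(float) for p in pts)))
            assert ours == pytest.approx(theirs, abs=1e-4)  # biotite uses float32

    def test_glycine_has_no_chi1(self):
        model = StructureModel([make_atom("CA", "C", 0, 0, 0, resname="GLY")])
        with pytest.raises(GeometryError):
            chi1(model, "A:1")


class TestContactsAndDistances:
    def make_pair(self, resname_a, name_a, elem_a, resname_b, name_b, elem_b, d):
        a = make_atom(name_a, elem_a, 0, 0, 0, chain="A", resname=resname_a)
        b = make_atom(name_b, elem_b, d, 0, 0, chain="B", resname=resname_b)
        return StructureModel([a]), StructureModel([b])

    def test_arg_asp_pair_is_ionic(self):
        # guanidino nitrogen vs carboxylate oxygen at 3.03 A
        a, b = self.make_pair("ARG", "NH1", "N", "ASP", "OD1", "O", 3.03)
        recs = contacts(a, b)
        assert len(recs) == 1 and recs[0].contact_class == "ionic"
        assert recs[0].distance == pytest.approx(3.03)

    def test_hbond_threshold_boundary(self):
        a, b = self.make_pair("SER", "N", "N", "GLY", "O", "O", 3.19)
        assert contacts(a, b)[0].contact_class == "hbond"
        a, b = self.make_pair("SER", "N", "N", "GLY", "O", "O", 3.21)
        assert contacts(a, b)[0].contact_class != "hbond"

    def test_carbon_pair_at_van_der_waals_range(self):
        a, b = self.make_pair("LEU", "CD1", "C", "PHE", "CZ", "C", 3.5)
        assert contacts(a, b)[0].contact_class == "vdw"

    def test_sub_vdw_close_approach(self):
        # nucleophile oxygen against a carbonyl carbon well below contact distance
        a, b = self.make_pair("SER", "OG", "O", "ARG", "C", "C", 1.6)
        assert contacts(a, b)[0].contact_class == "close_approach"

    def test_out_of_range_pairs_excluded(self):
        a, b = self.make_pair("LEU", "CD1", "C", "PHE", "CZ", "C", 4.5)
        assert contacts(a, b) == []

    def test_proline_backbone_n_not_a_donor(self):
        a, b = self.make_pair("PRO", "N", "N", "GLY", "O", "O", 3.0)
        assert contacts(a, b)[0].contact_class != "hbond"

    def test_atom_distance_and_ambiguity(self):
        model = StructureModel([
            make_atom("OG", "O", 0, 0, 0, resnum=741, resname="SER"),
            make_atom("C", "C", 1.0, 0, 0, resnum=17, resname="ARG"),
            make_atom("CA", "C", 2.0, 0, 0, resnum=17, resname="ARG"),
        ])
        assert atom_distance(model, "A:741:OG", "A:17:C") == pytest.approx(1.0)
        with pytest.raises(SelectionError):
            atom_distance(model, "A:741:OG", "A:17")


class TestAnglesAtCenter:
    def test_ideal_tetrahedron(self):
        s = 1 / math.sqrt(3)
        corners = [(s, s, s), (s, -s, -s), (-s, s, -s), (-s, -s, s)]
        atoms = [make_atom("C", "C", 0, 0, 0)] + [
            make_atom(f"H{i}", "O", *c, resnum=1) for i, c in enumerate(corners)
        ]
        angles, mean = angles_at_center(
            StructureModel(atoms), "A:1:C", [f"A:1:H{i}" for i in range(4)])
        assert len(angles) == 6
        assert mean == pytest.approx(109.4712, abs=1e-3)
        assert all(a == pytest.approx(109.4712, abs=1e-3) for a in angles)

    def test_right_angle(self):
        atoms = [make_atom("C", "C", 0, 0, 0),
                 make_atom("O1", "O", 1, 0, 0),
                 make_atom("O2", "O", 0, 1, 0)]
        angles, mean = angles_at_center(StructureModel(atoms), "A:1:C",
                                        ["A:1:O1", "A:1:O2"])
        assert angles == [pytest.approx(90.0)]

    def test_coincident_substituent_rejected(self):
        atoms = [make_atom("C", "C", 0, 0, 0), make_atom("O1", "O", 0, 0, 0, resnum=2)]
        with pytest.raises(GeometryError):
            angles_at_center(StructureModel(atoms), "A:1:C", ["A:2:O1", "A:2:O1"])


def quadrature_sasa(centers, radii, n=120_000, seed=0):
    """Brute-force spherical quadrature oracle for small sphere sets."""
    rng = np.random.default_rng(seed)
    total = 0.0
    for i, (c, r) in enumerate(zip(centers, radii)):
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = c + r * pts
        exposed = np.ones(n, dtype=bool)
        for j, (c2, r2) in enumerate(zip(centers, radii)):
            if i != j:
                exposed &= np.linalg.norm(pts - c2, axis=1) >= r2
        total += 4 * math.pi * r * r * exposed.mean()
    return total


class TestSasa:
    def test_single_sphere_analytic(self):
        model = StructureModel([make_atom("C1", "C", 0, 0, 0)])
        result = sasa(model, probe=1.4, slice_spacing=0.05)
        exact = 4 * math.pi * (CHOTHIA_RADII["C"] + 1.4) ** 2
        assert result.total == pytest.approx(exact, rel=0.005)
        assert result.total == pytest.approx(result.per_atom.sum())

    def test_disjoint_additivity(self):
        one = StructureModel([make_atom("C1", "C", 0, 0, 0)])
        two = StructureModel([make_atom("C1", "C", 0, 0, 0),
                              make_atom("C2", "C", 50, 0, 0, resnum=2)])
        a1 = sasa(one, slice_spacing=0.05).total
        a2 = sasa(two, slice_spacing=0.05).total
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_two_overlapping_spheres_vs_quadrature(self):
        offset = np.array([2.0, 0.5, 0.3])
        model = StructureModel([make_atom("C1", "C", 0, 0, 0),
                                make_atom("N1", "N", *offset, resnum=2)])
        ours = sasa(model, probe=1.4, slice_spacing=0.02).total
        oracle = quadrature_sasa(
            [np.zeros(3), offset],
            [CHOTHIA_RADII["C"] + 1.4, CHOTHIA_RADII["N"] + 1.4],
        )
        assert ours == pytest.approx(oracle, rel=0.01)

    def test_cross_check_against_shrake_rupley(self):
        """Independent algorithm (biotite Shrake-Rupley) agrees within 2%
        on a small cluster using the same radii."""
        import biotite.structure as struc

        rng = np.random.default_rng(9)
        coords = rng.normal(scale=2.5, size=(12, 3))
        elements = ["C", "N", "O", "S"] * 3
        model = StructureModel([
            make_atom(f"X{i}", el, *c, resnum=i + 1)
            for i, (el, c) in enumerate(zip(elements, coords))
        ])
        ours = sasa(model, probe=1.4, slice_spacing=0.02).total

        arr = struc.AtomArray(12)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(elements)
        arr.res_id = np.arange(1, 13)
        arr.atom_name = np.array([f"X{i}" for i in range(12)])
        arr.res_name = np.array(["GLY"] * 12)
        theirs = struc.sasa(
            arr, probe_radius=1.4, point_number=2000,
            vdw_radii=np.array([CHOTHIA_RADII[e] for e in elements]),
        ).sum()
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_unknown_element_raises(self):
        model = StructureModel([make_atom("FE", "Fe", 0, 0, 0)])
        with pytest.raises(GeometryError, match="Fe"):
            sasa(model)


class TestBuriedArea:
    def two_chain_complex(self, gap):
        rng = np.random.default_rng(4)
        a = rng.normal(scale=2.0, size=(8, 3))
        b = rng.normal(scale=2.0, size=(8, 3)) + [gap, 0.0, 0.0]
        atoms = [make_atom(f"A{i}", "C", *c, chain="A", resnum=i + 1)
                 for i, c in enumerate(a)]
        atoms += [make_atom(f"B{i}", "C", *c, chain="B", resnum=i + 1)
                  for i, c in enumerate(b)]
        return StructureModel(atoms)

    def test_separated_parts_bury_nothing(self):
        model = self.two_chain_complex(gap=60.0)
        assert buried_area(model, "A", "B", slice_spacing=0.05) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_and_positivity(self):
        model = self.two_chain_complex(gap=6.0)
        ab = buried_area(model, "A", "B", slice_spacing=0.05)
        ba = buried_area(model, "B", "A", slice_spacing=0.05)
        assert ab > 10.0
        assert ab == pytest.approx(ba, rel=1e-9)

    def test_overlapping_parts_rejected(self):
        model = self.two_chain_complex(gap=6.0)
        with pytest.raises(GeometryError):
            buried_area(model, ["A", "B"], "B")


class TestRigidMotionInvariance:
    def test_measurements_invariant_under_rigid_motion(self, toy_complex_pair):
        c1, c2 = toy_complex_pair
        angle0 = docking_angle(c1, c2, "E", "I")
        for seed in range(3):
            moved = rigid(c2, seed=seed)
            assert docking_angle(c1, moved, "E", "I") == pytest.approx(angle0, abs=1e-8)

    def test_sasa_and_angles_invariant(self):
        atoms = [
            make_atom("C", "C", 0, 0, 0),
            make_atom("O1", "O", 1.3, 0.2, -0.1, resnum=2),
            make_atom("N1", "N", -0.8, 1.1, 0.6, resnum=3),
            make_atom("S1", "S", 0.4, -1.2, 1.0, resnum=4),
        ]
        model = StructureModel(atoms)
        base_sasa = sasa(model, slice_spacing=0.02).total
        base_angle = angles_at_center(model, "A:1:C", ["A:2:O1", "A:3:N1"])[1]
        for seed in range(3):
            moved = rigid(model, seed=seed + 10)
            # slicing direction is fixed in space, so orientation changes
            # the discretization slightly; 0.5% reflects the method
            assert sasa(moved, slice_spacing=0.02).total == pytest.approx(
                base_sasa, rel=5e-3)
            assert angles_at_center(moved, "A:1:C", ["A:2:O1", "A:3:N1"])[1] == \
                pytest.approx(base_angle, abs=1e-8)
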