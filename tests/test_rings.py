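"""Ring mean plane, face classification, puckering, chi1 rotamers."""

import math

import numpy as np
import pytest

from tunnelflex.rings import (
    RING_ATOM_ORDER,
    chi1,
    classify_face,
    cremer_pople,
    dihedral,
    ring_conformation,
    ring_mean_plane,
    roof_reference_point,
    rotamer_bin,
    rotamer_transitions,
)
from tunnelflex.structure import Structure
from tunnelflex.synthetic import (
    make_bfactor_fixture,
    make_ring_fixture,
    make_sidechain_residue,
)


def ring_coords(structure):
    res = next(r for r in structure.iter_residues() if r.is_sugar)
    return np.array([res.atom(n).coord for n in RING_ATOM_ORDER])


def hexagon(radius=1.4):
    return np.array(
        [
            [radius * math.cos(math.radians(60 * k)),
             radius * math.sin(math.radians(60 * k)), 0.0]
            for k in range(6)
        ]
    )


class TestMeanPlane:
    def test_planar_hexagon_has_zero_displacements(self):
        _, normal, disp = ring_mean_plane(hexagon())
        np.testing.assert_allclose(disp, 0.0, atol=1e-12)
        assert np.linalg.norm(normal) == pytest.approx(1.0)

    def test_displacements_sum_to_zero_for_least_squares_plane(self):
        coords = ring_coords(make_ring_fixture("4C1"))
        _, _, disp = ring_mean_plane(coords)
        assert abs(disp.sum()) < 1e-6

    def test_chair_triads_alternate_sides_at_quarter_angstrom(self):
        coords = ring_coords(make_ring_fixture("4C1"))
        _, _, disp = ring_mean_plane(coords)
        triad, other = disp[[0, 2, 4]], disp[[1, 3, 5]]
        assert np.all(np.sign(triad) == np.sign(triad[0]))
        assert np.all(np.sign(other) == -np.sign(triad[0]))
        np.testing.assert_allclose(np.abs(disp), 0.25, atol=5e-3)

    def test_inverted_chair_flips_signs(self):
        d1 = ring_mean_plane(ring_coords(make_ring_fixture("4C1")))[2]
        d2 = ring_mean_plane(ring_coords(make_ring_fixture("1C4")))[2]
        # orient both normals the same way via the first ring atom
        if np.sign(d1[0]) == np.sign(d2[0]):
            d2 = -d2
        np.testing.assert_allclose(d1, -d2, atol=5e-3)

    def test_collinear_atoms_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(6)])
        with pytest.raises(ValueError, match="collinear|coincident"):
            ring_mean_plane(line)


class TestFaceClassification:
    def test_chair_face_follows_triad_sign_rule(self):
        coords = ring_coords(make_ring_fixture("4C1"))
        above = classify_face(coords, [0.0, 0.0, 10.0])
        below = classify_face(coords, [0.0, 0.0, -10.0])
        assert {above, below} == {"alpha", "beta"}
        # the 4C1 fixture puts C1/C3/C5 at +z
        assert above == "alpha"

    def test_reference_reflection_swaps_faces(self, rng):
        coords = ring_coords(make_ring_fixture("4C1"))
        centroid, normal, _ = ring_mean_plane(coords)
        ref = centroid + np.array([1.0, 2.0, 8.0])
        d = np.dot(ref - centroid, normal)
        mirrored = ref - 2 * d * normal
        faces = {classify_face(coords, ref), classify_face(coords, mirrored)}
        assert faces == {"alpha", "beta"}

    def test_mirror_conformer_shows_opposite_face(self):
        ref = [0.0, 0.0, 10.0]
        f1 = classify_face(ring_coords(make_ring_fixture("4C1")), ref)
        f2 = classify_face(ring_coords(make_ring_fixture("1C4")), ref)
        assert {f1, f2} == {"alpha", "beta"}

    def test_planar_and_half_chair_indeterminate(self):
        assert classify_face(hexagon(), [0, 0, 10]) == "indeterminate"
        coords = ring_coords(make_ring_fixture("half_chair"))
        assert classify_face(coords, [0, 0, 10]) == "indeterminate"

    def test_reference_on_plane_rejected(self):
        coords = ring_coords(make_ring_fixture("4C1"))
        centroid, normal, _ = ring_mean_plane(coords)
        with pytest.raises(ValueError, match="0.1"):
            classify_face(coords, centroid + 0.05 * normal)

    def test_rigid_motion_of_ring_and_reference_together(self, rng):
        coords = ring_coords(make_ring_fixture("4C1"))
        ref = np.array([0.5, -0.5, 9.0])
        face = classify_face(coords, ref)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = np.array([3.0, -7.0, 12.0])
        assert classify_face(coords @ q.T + t, q @ ref + t) == face

    def test_chair_is_never_indeterminate(self):
        for conformer in ("4C1", "1C4"):
            coords = ring_coords(make_ring_fixture(conformer))
            for ref in ([0, 0, 10], [2, 3, -8], [-4, 1, 6]):
                assert classify_face(coords, ref) in ("alpha", "beta")

    def test_ring_conformation_via_residue_and_roof_reference(self):
        ring = make_ring_fixture("4C1")
        res = next(r for r in ring.iter_residues())
        roof = make_bfactor_fixture(
            b_profile=15.0, residue_ids=["Y38", "Y39"]
        )
        # hoist the roof above the ring so the reference is off-plane
        roof = roof.transformed(np.eye(3), np.array([0.0, 0.0, 9.0]))
        st = Structure(chains={**roof.chains, **ring.chains})
        conf = ring_conformation(res, roof_reference_point(st))
        assert conf.face == "alpha"
        assert np.linalg.norm(conf.normal) == pytest.approx(1.0)


class TestCremerPople:
    def test_ideal_chair_is_pure_chair_phase(self):
        Q, theta, phi = cremer_pople(ring_coords(make_ring_fixture("4C1")))
        assert Q > 0.4
        assert min(theta, 180 - theta) < 5.0   # at a chair pole

    def test_planar_ring_has_zero_amplitude(self):
        Q, _, _ = cremer_pople(hexagon())
        assert Q == pytest.approx(0.0, abs=1e-12)


class TestChi1:
    @pytest.mark.parametrize(
        "angle,expected_bin",
        [(180.0, "t"), (-60.0, "g-"), (60.0, "g+"), (-150.0, "t"), (100.0, "g+")],
    )
    def test_constructed_torsion_recovered_and_binned(self, angle, expected_bin):
        res = make_sidechain_residue("LYS", 42, chi1_deg=angle)
        state = chi1(res)
        assert state.chi1 == pytest.approx(angle, abs=1e-6)
        assert state.rotamer_bin == expected_bin

    def test_glycine_unresolved(self):
        res = make_bfactor_fixture(b_profile=10.0, residue_ids=["G306"]).residue(
            "A", 306
        )
        assert chi1(res).rotamer_bin == "unresolved"

    def test_dihedral_two_route_agreement(self, rng):
        # independent route: plane-normal cross products with signed atan2
        def dihedral_alt(p0, p1, p2, p3):
            b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            b2n = b2 / np.linalg.norm(b2)
            x = np.dot(n1, n2)
            y = np.dot(np.cross(n1, n2), b2n)
            return math.degrees(math.atan2(y, x))

        for _ in range(25):
            pts = rng.normal(scale=3.0, size=(4, 3))
            if min(np.linalg.norm(pts[i + 1] - pts[i]) for i in range(3)) < 0.5:
                continue
            a = dihedral(*pts)
            b = dihedral_alt(*pts)
            assert a == pytest.approx(b, abs=1e-6)

    def test_bin_edges(self):
        # half-open wells: g+ = (0,120], t = (120,180] u (-180,-120], g- = (-120,0]
        assert rotamer_bin(120.0) == "g+"
        assert rotamer_bin(120.0001) == "t"
        assert rotamer_bin(-120.0) == "t"
        assert rotamer_bin(-119.9999) == "g-"
        assert rotamer_bin(0.0) == "g-"
        assert rotamer_bin(180.0) == "t"


class TestRotamerTransitions:
    def _structure_with_chi(self, chi_map):
        residues = [
            make_sidechain_residue(name, seq, chi, origin=np.array([6.0 * i, 0, 0]))
            for i, (name, seq, chi) in enumerate(chi_map)
        ]
        return Structure(chains={"A": residues})

    def test_identical_structures_show_no_transitions(self):
        spec = [("LYS", 42, -60.0), ("ARG", 163, 175.0)]
        st1 = self._structure_with_chi(spec)
        st2 = self._structure_with_chi(spec)
        table = rotamer_transitions({"pH5": st1, "pH7": st2}, (42, 163))
        assert all(not any(row["changed"].values()) for row in table.values())

    def test_single_120_degree_flip_flagged_once(self):
        st1 = self._structure_with_chi([("LYS", 42, -60.0), ("ARG", 163, 175.0)])
        st2 = self._structure_with_chi([("LYS", 42, 60.0), ("ARG", 163, 175.0)])
        table = rotamer_transitions({"pH5": st1, "pH7": st2}, (42, 163))
        flags = [table[seq]["changed"]["pH7"] for seq in (42, 163)]
        assert flags == [True, False]

    def test_missing_residue_reported_unresolved_and_changed(self):
        st1 = self._structure_with_chi([("LYS", 42, -60.0)])
        st2 = self._structure_with_chi([("ARG", 163, 175.0)])  # no K42
        table = rotamer_transitions({"pH5": st1, "pH7": st2}, (42,))
        assert table[42]["bins"]["pH7"] == "unresolved"
        assert table[42]["changed"]["pH7"] is True

    def test_residue_absent_everywhere_skipped(self):
        st1 = self._structure_with_chi([("LYS", 42, -60.0)])
        st2 = self._structure_with_chi([("LYS", 42, -60.0)])
        table = rotamer_transitions({"a": st1, "b": st2}, (42, 999))
        assert 999 not in table

    def test_requires_two_structures(self):
        st1 = self._structure_with_chi([("LYS", 42, -60.0)])
        with pytest.raises(ValueError, match="two"):
            rotamer_transitions({"only": st1}, (42,))
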