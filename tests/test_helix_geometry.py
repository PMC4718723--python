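"""Ideal-helix construction and rod-axis geometry."""

import math

import numpy as np
import pytest

from helixtrace.helix_geometry import (
    BackboneModel,
    HelixBuildParams,
    RodAxis,
    build_ideal_helix,
    fit_axis,
    helix_parameters,
    place_helix,
    read_pdb,
    segment_distance,
    write_pdb,
)


def dihedral(a, b, c, d):
    """Independent IUPAC-convention dihedral oracle (gemmi)."""
    import gemmi

    pos = [gemmi.Position(*x) for x in (a, b, c, d)]
    return math.degrees(gemmi.calculate_dihedral(*pos))


class TestBuilder:
    def test_atom_counts(self):
        h = build_ideal_helix(10)
        assert len(h) == 10
        assert h.coords.shape == (10, 4, 3)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            build_ideal_helix(0)

    def test_first_three_atoms_hand_computed(self):
        # independent oracle: the canonical frame places N at the origin,
        # Cα at bond length on +x, and C in the xy-plane at the N-Cα-C angle
        p = HelixBuildParams()
        h = build_ideal_helix(3, p)
        n0, ca0, c0 = h.coords[0, 0], h.coords[0, 1], h.coords[0, 2]
        assert np.allclose(n0, [0, 0, 0])
        assert np.allclose(ca0, [p.bond_n_ca, 0, 0])
        assert np.isclose(np.linalg.norm(c0 - ca0), p.bond_ca_c)
        cos_angle = ((n0 - ca0) @ (c0 - ca0)) / (p.bond_n_ca * p.bond_ca_c)
        assert np.isclose(math.degrees(math.acos(cos_angle)), p.angle_n_ca_c)

    def test_build_respects_dihedrals(self):
        p = HelixBuildParams()
        h = build_ideal_helix(5, p)
        n, ca, c = (h.coords[:, i] for i in range(3))

        def wrap_diff(x, y):
            return (x - y + 180.0) % 360.0 - 180.0

        for i in range(4):
            assert abs(wrap_diff(dihedral(n[i], ca[i], c[i], n[i + 1]), p.psi)) < 1e-6
            assert abs(wrap_diff(dihedral(ca[i], c[i], n[i + 1], ca[i + 1]), p.omega)) < 1e-6
            assert abs(wrap_diff(dihedral(c[i], n[i + 1], ca[i + 1], c[i + 1]), p.phi)) < 1e-6

    def test_consecutive_ca_distance(self, helix36):
        d = np.linalg.norm(np.diff(helix36.ca, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.1)
        assert np.all((d > 3.6) & (d < 4.0))

    def test_canonical_helix_parameters(self, helix36):
        params = helix_parameters(helix36)
        assert params["rise"] == pytest.approx(1.5, abs=0.1)
        assert params["residues_per_turn"] == pytest.approx(3.6, abs=0.2)
        assert params["radius"] == pytest.approx(2.3, abs=0.2)


class TestFitAxis:
    def test_collinear_points(self):
        ca = np.stack([np.zeros(10), np.zeros(10), np.arange(10.0)], axis=1)
        coords = np.repeat(ca[:, None, :], 4, axis=1)
        model = BackboneModel(np.arange(1, 11), coords)
        axis = fit_axis(model)
        assert np.allclose(axis.direction, [0, 0, 1])
        radial = model.ca - np.outer(model.ca @ axis.direction, axis.direction)
        assert np.allclose(radial - radial[0], 0, atol=1e-9)

    def test_coincident_points_rejected(self):
        coords = np.zeros((5, 4, 3))
        with pytest.raises(ValueError):
            fit_axis(BackboneModel(np.arange(1, 6), coords))

    def test_helix_radius_about_axis(self, helix30):
        axis = fit_axis(helix30)
        centroid = helix30.ca.mean(axis=0)
        rel = helix30.ca - centroid
        radial = rel - np.outer(rel @ axis.direction, axis.direction)
        assert np.linalg.norm(radial, axis=1).mean() == pytest.approx(2.3, abs=0.2)

    def test_axis_length_matches_rise(self, helix30):
        params = helix_parameters(helix30)
        expected = (len(helix30) - 1) * params["rise"]
        assert fit_axis(helix30).length == pytest.approx(expected, rel=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equivariance_under_rigid_motion(self, helix30, seed):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        trans = rng.normal(scale=15.0, size=3)
        moved = helix30.transformed(rot, trans)
        a0 = fit_axis(helix30)
        a1 = fit_axis(moved)
        assert np.allclose(a1.endpoint_a, rot @ a0.endpoint_a + trans, atol=1e-8)
        assert np.allclose(a1.endpoint_b, rot @ a0.endpoint_b + trans, atol=1e-8)


class TestPlaceHelix:
    rod = RodAxis(np.array([10.0, 0.0, -15.0]), np.array([10.0, 0.0, 15.0]))

    def test_direction_flip_swaps_ends(self):
        fwd = place_helix(20, self.rod, "forward")
        rev = place_helix(20, self.rod, "reverse")
        da_f = np.linalg.norm(fwd.ca[0] - self.rod.endpoint_a)
        db_f = np.linalg.norm(fwd.ca[-1] - self.rod.endpoint_b)
        da_r = np.linalg.norm(rev.ca[-1] - self.rod.endpoint_a)
        db_r = np.linalg.norm(rev.ca[0] - self.rod.endpoint_b)
        assert abs(da_f - da_r) < 0.5 and abs(db_f - db_r) < 0.5

    def test_register_shift_slides_along_axis(self):
        base = place_helix(20, self.rod)
        shifted = place_helix(20, self.rod, register_shift=1)
        delta = shifted.ca - base.ca
        along = delta @ self.rod.direction
        assert np.allclose(np.linalg.norm(delta, axis=1), along, atol=1e-9)
        assert np.all(np.abs(along - 1.5) < 0.1)

    def test_full_roll_is_identity(self):
        base = place_helix(20, self.rod, roll=0.0)
        turned = place_helix(20, self.rod, roll=360.0)
        assert np.allclose(base.coords, turned.coords, atol=1e-6)

    def test_rigid_placement_preserves_distances(self):
        h = build_ideal_helix(20)
        placed = place_helix(20, self.rod, "reverse", 2, 110.0)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(h.ca), pdist(placed.ca), atol=1e-6)

    def test_place_onto_own_axis_roundtrip(self, helix30):
        axis = fit_axis(helix30)
        replaced = place_helix(30, axis, "forward", 0, 0.0)
        rmsd = np.sqrt(np.mean(np.sum((replaced.ca - helix30.ca) ** 2, axis=1)))
        assert rmsd < 0.1

    def test_register_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            place_helix(10, self.rod, register_shift=11)


class TestSegmentDistance:
    def test_parallel_segments(self):
        d = segment_distance([0, 0, 0], [0, 0, 10], [5, 0, 0], [5, 0, 10])
        assert d == pytest.approx(5.0)

    def test_skew_clamped_to_endpoints(self):
        d = segment_distance([0, 0, 0], [1, 0, 0], [5, 0, 0], [9, 0, 0])
        assert d == pytest.approx(4.0)


class TestPdbIO:
    def test_roundtrip_chains(self, tmp_path, helix30):
        partner = build_ideal_helix(12, first_residue=101)
        path = tmp_path / "model.pdb"
        write_pdb(path, {"A": helix30, "C": partner})
        back = read_pdb(path)
        assert set(back) == {"A", "C"}
        assert np.array_equal(back["A"].numbers, helix30.numbers)
        assert np.allclose(back["A"].coords, helix30.coords, atol=1e-3)
        assert np.allclose(back["C"].coords, partner.coords, atol=1e-3)
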