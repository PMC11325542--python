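import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hispi import ring_geometry as rg
from hispi import synthetic_data as sd
from hispi.structure_io import Atom, Residue

from conftest import hexagon_residue, random_rotation, transform
from oracles import aromatic_descriptors, cation_descriptors


@given(st.floats(min_value=-720.0, max_value=720.0))
def test_fold90_range(angle):
    folded = rg.fold90(angle)
    assert 0.0 <= folded <= 90.0


def test_fold90_examples():
    assert rg.fold90(120.0) == pytest.approx(60.0)
    assert rg.fold90(90.0) == pytest.approx(90.0)
    assert rg.fold90(0.0) == 0.0


class TestBuildRing:
    def test_perfect_hexagon(self):
        ring = rg.build_ring(hexagon_residue())
        np.testing.assert_allclose(ring.centroid, np.zeros(3), atol=1e-12)
        assert abs(abs(ring.normal[2]) - 1.0) < 1e-12
        assert ring.planarity_rmsd < 1e-12

    def test_displaced_atom_breaches_tolerance(self):
        res = hexagon_residue()
        res.atoms[0] = dataclasses.replace(
            res.atoms[0], coords=res.atoms[0].coords + np.array([0.0, 0.0, 0.5])
        )
        with pytest.raises(rg.RingBuildError, match="planarity"):
            rg.build_ring(res, planarity_tol=0.1)

    def test_missing_atom(self):
        res = hexagon_residue()
        res.atoms = res.atoms[:-1]
        with pytest.raises(rg.RingBuildError, match="missing"):
            rg.build_ring(res)

    def test_rotated_hexagon_normal(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            rot = random_rotation(rng)
            shift = rng.uniform(-20, 20, 3)
            ring = rg.build_ring(transform(hexagon_residue(), rot, shift))
            assert ring.planarity_rmsd < 1e-9
            expected = rot @ np.array([0.0, 0.0, 1.0])
            assert min(
                np.linalg.norm(ring.normal - expected),
                np.linalg.norm(ring.normal + expected),
            ) < 1e-9

    def test_unknown_residue(self):
        res = hexagon_residue(name="GLY")
        with pytest.raises(rg.RingBuildError):
            rg.build_ring(res)


class TestAromaticPairGeometry:
    def test_face_to_face_stack(self):
        a = rg.build_ring(hexagon_residue(z=0.0))
        b = rg.build_ring(hexagon_residue(z=3.5))
        g = rg.aromatic_pair_geometry(a, b)
        assert g.D == pytest.approx(3.5)
        assert g.P == pytest.approx(0.0, abs=1e-9)
        assert g.T_theta1 == pytest.approx(90.0)
        assert g.T_theta2 == pytest.approx(90.0)

    def test_coplanar(self):
        a = rg.build_ring(hexagon_residue())
        shifted = transform(hexagon_residue(), np.eye(3), [5.0, 0.0, 0.0])
        g = rg.aromatic_pair_geometry(a, rg.build_ring(shifted))
        assert g.D == pytest.approx(5.0)
        assert g.P == pytest.approx(0.0, abs=1e-9)
        assert g.T_theta1 == pytest.approx(0.0, abs=1e-9)
        assert g.T_theta2 == pytest.approx(0.0, abs=1e-9)

    def test_coincident_centroids(self):
        a = rg.build_ring(hexagon_residue())
        with pytest.raises(ValueError, match="coincident"):
            rg.aromatic_pair_geometry(a, a)

    def test_random_poses_match_oracle(self, his_template, phe_template):
        rng = np.random.default_rng(23)
        for _ in range(200):
            ra = transform(his_template, random_rotation(rng), rng.uniform(-10, 10, 3))
            rb = transform(phe_template, random_rotation(rng), rng.uniform(-10, 10, 3))
            ring_a, ring_b = rg.build_ring(ra), rg.build_ring(rb)
            if np.linalg.norm(ring_a.centroid - ring_b.centroid) < 0.5:
                continue
            g = rg.aromatic_pair_geometry(ring_a, ring_b)
            coords_a = [ra.get_atom(n).coords for n in rg.RING_ATOMS["HIS"]]
            coords_b = [rb.get_atom(n).coords for n in rg.RING_ATOMS["PHE"]]
            D, P, t1, t2 = aromatic_descriptors(coords_a, coords_b)
            assert g.D == pytest.approx(D, abs=1e-6)
            assert g.P == pytest.approx(P, abs=1e-6)
            assert g.T_theta1 == pytest.approx(t1, abs=1e-6)
            assert g.T_theta2 == pytest.approx(t2, abs=1e-6)


class TestSymmetryInvariants:
    def _random_rings(self, rng, his_template, phe_template):
        ra = transform(his_template, random_rotation(rng), rng.uniform(-10, 10, 3))
        rb = transform(phe_template, random_rotation(rng), rng.uniform(-10, 10, 3))
        return ra, rb

    def test_swap_symmetry(self, his_template, phe_template):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ra, rb = self._random_rings(rng, his_template, phe_template)
            A, B = rg.build_ring(ra), rg.build_ring(rb)
            if np.linalg.norm(A.centroid - B.centroid) < 0.5:
                continue
            g_ab = rg.aromatic_pair_geometry(A, B)
            g_ba = rg.aromatic_pair_geometry(B, A)
            assert abs(g_ab.D - g_ba.D) < 1e-9
            assert abs(g_ab.P - g_ba.P) < 1e-9
            assert abs(g_ab.T_theta1 - g_ba.T_theta2) < 1e-9
            assert abs(g_ab.T_theta2 - g_ba.T_theta1) < 1e-9

    def test_rigid_body_invariance(self, his_template, phe_template):
        rng = np.random.default_rng(6)
        ra, rb = self._random_rings(rng, his_template, phe_template)
        g0 = rg.aromatic_pair_geometry(rg.build_ring(ra), rg.build_ring(rb))
        for _ in range(25):
            rot, shift = random_rotation(rng), rng.uniform(-50, 50, 3)
            g = rg.aromatic_pair_geometry(
                rg.build_ring(transform(ra, rot, shift)),
                rg.build_ring(transform(rb, rot, shift)),
            )
            for attr in ("D", "P", "T_theta1", "T_theta2"):
                assert abs(getattr(g, attr) - getattr(g0, attr)) < 1e-6

    def test_atom_order_reversal(self, his_template, phe_template):
        rng = np.random.default_rng(7)
        ra, rb = self._random_rings(rng, his_template, phe_template)
        reversed_b = dataclasses.replace(rb, atoms=list(reversed(rb.atoms)))
        g0 = rg.aromatic_pair_geometry(rg.build_ring(ra), rg.build_ring(rb))
        g1 = rg.aromatic_pair_geometry(rg.build_ring(ra), rg.build_ring(reversed_b))
        for attr in ("D", "P", "T_theta1", "T_theta2"):
            assert abs(getattr(g0, attr) - getattr(g1, attr)) < 1e-9

    def test_angles_in_range(self, his_template, phe_template):
        rng = np.random.default_rng(8)
        for _ in range(100):
            ra, rb = self._random_rings(rng, his_template, phe_template)
            A, B = rg.build_ring(ra), rg.build_ring(rb)
            if np.linalg.norm(A.centroid - B.centroid) < 0.5:
                continue
            g = rg.aromatic_pair_geometry(A, B)
            assert 0.0 <= g.P <= 90.0
            assert 0.0 <= g.T_theta1 <= 90.0
            assert 0.0 <= g.T_theta2 <= 90.0


class TestCationPiGeometry:
    def test_on_axis(self):
        ring = rg.build_ring(hexagon_residue())
        site = rg.CationSite("A:2", "LYS", "NZ", np.array([0.0, 0.0, 4.0]))
        g = rg.cation_pi_geometry(ring, site)
        assert g.D == pytest.approx(4.0)
        assert g.theta1 == pytest.approx(0.0, abs=1e-9)
        assert g.theta2 is None

    def test_in_plane(self):
        ring = rg.build_ring(hexagon_residue())
        site = rg.CationSite("A:2", "LYS", "NZ", np.array([5.0, 0.0, 0.0]))
        g = rg.cation_pi_geometry(ring, site)
        assert g.theta1 == pytest.approx(90.0)

    def test_random_vs_oracle(self, phe_template):
        rng = np.random.default_rng(31)
        arg = sd.make_residue_template("ARG")
        for _ in range(100):
            ring_res = transform(phe_template, random_rotation(rng), rng.uniform(-10, 10, 3))
            cat_res = transform(arg, random_rotation(rng), rng.uniform(-10, 10, 3))
            ring = rg.build_ring(ring_res)
            site = rg.cation_site(cat_res)
            if np.linalg.norm(site.center - ring.centroid) < 0.5:
                continue
            g = rg.cation_pi_geometry(ring, site)
            plane = [cat_res.get_atom(n).coords for n in ("NE", "CZ", "NH1", "NH2")]
            D, t1, t2 = cation_descriptors(
                [ring_res.get_atom(n).coords for n in rg.RING_ATOMS["PHE"]],
                site.center,
                plane,
            )
            assert g.D == pytest.approx(D, abs=1e-6)
            assert g.theta1 == pytest.approx(t1, abs=1e-6)
            assert g.theta2 == pytest.approx(t2, abs=1e-6)


class TestHisPlusCationSite:
    def test_ne2_nearer(self, his_template):
        ne2 = his_template.get_atom("NE2").coords
        target = ne2 + np.array([0.0, 0.0, 3.5])
        site = rg.his_plus_cation_site(his_template, target)
        assert site.chosen_nitrogen == "NE2"

    def test_nd1_nearer(self, his_template):
        nd1 = his_template.get_atom("ND1").coords
        target = nd1 + np.array([0.0, 0.0, 3.5])
        site = rg.his_plus_cation_site(his_template, target)
        assert site.chosen_nitrogen == "ND1"

    def test_tie_prefers_ne2(self, his_template):
        ne2 = his_template.get_atom("NE2").coords
        nd1 = his_template.get_atom("ND1").coords
        midpoint = (ne2 + nd1) / 2 + np.array([0.0, 0.0, 4.0])
        # equidistant by construction (both N in z=0 plane)
        assert np.linalg.norm(midpoint - ne2) == pytest.approx(np.linalg.norm(midpoint - nd1))
        site = rg.his_plus_cation_site(his_template, midpoint)
        assert site.chosen_nitrogen == "NE2"

    def test_missing_nitrogen(self, his_template):
        broken = dataclasses.replace(
            his_template, atoms=[a for a in his_template.atoms if a.name != "NE2"]
        )
        with pytest.raises(rg.RingBuildError):
            rg.his_plus_cation_site(broken, np.zeros(3))


class TestAddIdealHydrogens:
    def _ring_nh(self, res):
        out = {}
        for n_name in ("ND1", "NE2"):
            n = res.get_atom(n_name)
            out[n_name] = [
                h for h in res.hydrogens()
                if np.linalg.norm(h.coords - n.coords) <= 1.2
            ]
        return out

    def test_hie_single_nh_on_ne2_in_plane(self, his_template):
        res = rg.add_ideal_hydrogens(his_template, "HIE")
        nh = self._ring_nh(res)
        assert len(nh["NE2"]) == 1 and len(nh["ND1"]) == 0
        ring = rg.build_ring(res)
        h = nh["NE2"][0]
        assert abs(np.dot(h.coords - ring.centroid, ring.normal)) < 1e-6

    def test_hid(self, his_template):
        nh = self._ring_nh(rg.add_ideal_hydrogens(his_template, "HID"))
        assert len(nh["ND1"]) == 1 and len(nh["NE2"]) == 0

    def test_hip_both(self, his_template):
        nh = self._ring_nh(rg.add_ideal_hydrogens(his_template, "HIP"))
        assert len(nh["ND1"]) == 1 and len(nh["NE2"]) == 1

    def test_ch_lengths(self, phe_template):
        res = rg.add_ideal_hydrogens(phe_template, "aromatic_CH_only")
        for h in res.hydrogens():
            heavy = min(
                (a for a in res.heavy_atoms()),
                key=lambda a: np.linalg.norm(a.coords - h.coords),
            )
            expected = 0.96 if heavy.name == "OH" else (1.01 if heavy.element == "N" else 1.08)
            assert np.linalg.norm(h.coords - heavy.coords) == pytest.approx(expected, abs=1e-6)

    def test_lysine_ammonium(self):
        lys = sd.make_residue_template("LYS")
        res = rg.add_ideal_hydrogens(lys, "lys_NZ3")
        nz = res.get_atom("NZ")
        ce = res.get_atom("CE")
        hs = [h for h in res.hydrogens() if np.linalg.norm(h.coords - nz.coords) <= 1.2]
        assert len(hs) == 3
        for h in hs:
            assert np.linalg.norm(h.coords - nz.coords) == pytest.approx(1.01, abs=1e-6)
            u = ce.coords - nz.coords
            v = h.coords - nz.coords
            angle = math.degrees(
                math.acos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            )
            assert angle == pytest.approx(109.47, abs=0.01)

    def test_replaces_existing_hydrogens(self, his_template):
        once = rg.add_ideal_hydrogens(his_template, "HIP")
        twice = rg.add_ideal_hydrogens(once, "HIE")
        nh = self._ring_nh(twice)
        assert len(nh["ND1"]) == 0 and len(nh["NE2"]) == 1

    def test_invalid_scenario(self, phe_template):
        with pytest.raises(ValueError):
            rg.add_ideal_hydrogens(phe_template, "HIE")

    def test_missing_anchor(self, his_template):
        broken = dataclasses.replace(
            his_template, atoms=[a for a in his_template.atoms if a.name != "CE1"]
        )
        with pytest.raises((ValueError, rg.RingBuildError)):
            rg.add_ideal_hydrogens(broken, "HIE")
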