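import dataclasses
import math

import numpy as np
import pytest

from hispi import pair_mining as pm
from hispi import protonation as pr
from hispi import ring_geometry as rg
from hispi import synthetic_data as sd

from conftest import random_rotation, transform

CANONICAL_RING_BONDS = {"HIS": 1.37, "PHE": 1.39, "TYR": 1.39}


class TestTemplates:
    @pytest.mark.parametrize("name", ["HIS", "PHE", "TYR", "TRP"])
    def test_ring_planarity(self, name):
        ring = rg.build_ring(sd.make_residue_template(name))
        assert ring.planarity_rmsd < 1e-6

    @pytest.mark.parametrize("name", ["HIS", "PHE", "TYR"])
    def test_ring_bond_lengths(self, name):
        res = sd.make_residue_template(name)
        for a, b in rg.RING_BONDS[name]:
            d = np.linalg.norm(res.get_atom(a).coords - res.get_atom(b).coords)
            assert abs(d - CANONICAL_RING_BONDS[name]) < 0.05

    def test_trp_bond_lengths(self):
        res = sd.make_residue_template("TRP")
        for a, b in rg.RING_BONDS["TRP"]:
            d = np.linalg.norm(res.get_atom(a).coords - res.get_atom(b).coords)
            assert 1.30 < d < 1.45

    def test_his_hie_has_single_ring_nh(self):
        res = sd.make_residue_template("HIS", "HIE")
        ne2 = res.get_atom("NE2").coords
        nd1 = res.get_atom("ND1").coords
        on_ne2 = [h for h in res.hydrogens() if np.linalg.norm(h.coords - ne2) <= 1.2]
        on_nd1 = [h for h in res.hydrogens() if np.linalg.norm(h.coords - nd1) <= 1.2]
        assert len(on_ne2) == 1 and len(on_nd1) == 0

    def test_phe_five_ring_hydrogens(self):
        res = sd.make_residue_template("PHE", "aromatic_CH_only")
        assert len(res.hydrogens()) == 5

    def test_invalid_combination(self):
        with pytest.raises(ValueError):
            sd.make_residue_template("PHE", "HIE")
        with pytest.raises(ValueError):
            sd.make_residue_template("ALA")


def _random_feasible_aromatic_targets(rng, his, phe):
    """Sample a random rigid pose, measure it — guarantees feasibility."""
    posed = transform(phe, random_rotation(rng), rng.uniform(2.5, 8.0) * _unit_vec(rng))
    g = rg.aromatic_pair_geometry(rg.build_ring(his), rg.build_ring(posed))
    return g.D, g.P, g.T_theta2, g.T_theta1


def _unit_vec(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestPlaceAromaticPair:
    def test_p_zero_forces_equal_elevations(self, his_template, phe_template):
        s = sd.place_aromatic_pair(his_template, phe_template, 4.0, 0.0, 90.0)
        g = rg.aromatic_pair_geometry(
            rg.build_ring(s.residues[0]), rg.build_ring(s.residues[1])
        )
        assert g.D == pytest.approx(4.0, abs=1e-9)
        assert g.P == pytest.approx(0.0, abs=1e-9)
        assert g.T_theta1 == g.T_theta2  # geometric necessity, exact

    def test_favorable_stack_region(self, his_template, phe_template):
        s = sd.place_aromatic_pair(his_template, phe_template, 3.8, 10.0, 70.0)
        g = rg.aromatic_pair_geometry(
            rg.build_ring(s.residues[0]), rg.build_ring(s.residues[1])
        )
        assert g.D == pytest.approx(3.8, abs=1e-3)
        assert g.P == pytest.approx(10.0, abs=1e-3)
        assert g.T_theta2 == pytest.approx(70.0, abs=1e-3)

    def test_random_feasible_targets_round_trip(self, his_template, phe_template):
        rng = np.random.default_rng(51)
        for _ in range(150):
            D, P, t2, t1 = _random_feasible_aromatic_targets(rng, his_template, phe_template)
            s = sd.place_aromatic_pair(his_template, phe_template, D, P, t2, t1)
            g = rg.aromatic_pair_geometry(
                rg.build_ring(s.residues[0]), rg.build_ring(s.residues[1])
            )
            assert g.D == pytest.approx(D, abs=1e-3)
            assert g.P == pytest.approx(P, abs=1e-3)
            assert g.T_theta2 == pytest.approx(t2, abs=1e-3)
            assert g.T_theta1 == pytest.approx(t1, abs=1e-3)

    def test_free_t1_round_trip(self, his_template, phe_template):
        rng = np.random.default_rng(52)
        for _ in range(100):
            D, P, t2 = rng.uniform(3, 8), rng.uniform(0, 90), rng.uniform(0, 90)
            s = sd.place_aromatic_pair(his_template, phe_template, D, P, t2)
            g = rg.aromatic_pair_geometry(
                rg.build_ring(s.residues[0]), rg.build_ring(s.residues[1])
            )
            assert g.D == pytest.approx(D, abs=1e-3)
            assert g.P == pytest.approx(P, abs=1e-3)
            assert g.T_theta2 == pytest.approx(t2, abs=1e-3)

    def test_infeasible_combination(self, his_template, phe_template):
        # |Tθ1 − Tθ2| far beyond P cannot be realized
        with pytest.raises(sd.InfeasibleGeometryError):
            sd.place_aromatic_pair(his_template, phe_template, 4.0, 5.0, 80.0, 10.0)

    def test_too_close(self, his_template, phe_template):
        with pytest.raises(sd.InfeasibleGeometryError):
            sd.place_aromatic_pair(his_template, phe_template, 1.0, 0.0, 90.0)


class TestPlaceCationPair:
    def test_lys_on_axis(self, phe_template):
        lys = sd.make_residue_template("LYS")
        s = sd.place_cation_pair(phe_template, lys, 4.0, 0.0)
        ring = rg.build_ring(s.residues[0])
        site = rg.cation_site(s.residues[1], partner_centroid=ring.centroid)
        g = rg.cation_pi_geometry(ring, site)
        assert g.D == pytest.approx(4.0, abs=1e-9)
        assert g.theta1 == pytest.approx(0.0, abs=1e-6)

    def test_his_cation_prefers_ne2(self, phe_template):
        his = sd.make_residue_template("HIS")
        s = sd.place_cation_pair(phe_template, his, 4.5, 30.0, 40.0)
        ring = rg.build_ring(s.residues[0])
        site = rg.cation_site(s.residues[1], partner_centroid=ring.centroid)
        assert site.chosen_nitrogen == "NE2"

    def test_random_targets_round_trip(self, phe_template):
        rng = np.random.default_rng(53)
        for cat_name in ("LYS", "ARG", "HIS"):
            cat = sd.make_residue_template(cat_name)
            for _ in range(60):
                D, t1 = rng.uniform(3, 7), rng.uniform(0, 90)
                t2 = None if cat_name == "LYS" else rng.uniform(0, 90)
                s = sd.place_cation_pair(phe_template, cat, D, t1, t2)
                ring = rg.build_ring(s.residues[0])
                site = rg.cation_site(s.residues[1], partner_centroid=ring.centroid)
                g = rg.cation_pi_geometry(ring, site)
                assert g.D == pytest.approx(D, abs=1e-3)
                assert g.theta1 == pytest.approx(t1, abs=1e-3)
                if t2 is not None:
                    assert g.theta2 == pytest.approx(t2, abs=1e-3)

    def test_lys_theta2_rejected(self, phe_template):
        lys = sd.make_residue_template("LYS")
        with pytest.raises(sd.InfeasibleGeometryError, match="no cation plane"):
            sd.place_cation_pair(phe_template, lys, 4.0, 0.0, 30.0)


class TestMakeFixtureStructure:
    def test_mining_golden(self, mining_fixture):
        _, structure, echo = mining_fixture
        mined = pm.mine(structure)
        unique = {frozenset((p.ref_id, p.partner_id)) for p in mined}
        assert len(unique) == 1

    def test_census_golden(self):
        manifest = sd.FixtureManifest(
            deuterated={"epsilon0": 12, "delta0": 6, "positive": 9}
        )
        s, echo = sd.make_fixture_structure(manifest)
        from hispi.ensemble_stats import tautomer_census
        counts = tautomer_census([s])
        assert (counts["epsilon0"], counts["delta0"], counts["positive"]) == (12, 6, 9)

    def test_microenv_golden(self):
        manifest = sd.FixtureManifest(
            microenvironments=[sd.MicroEnvSpec("acceptor_nd1")]
        )
        s, echo = sd.make_fixture_structure(manifest)
        his = s.find_residue(echo["microenvironments"][0]["his_id"])
        call = pr.infer_protonation_hbond(s, his)
        assert call.state == "neutral" and call.tautomer == "epsilon0"

    def test_spacing_too_small_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            sd.FixtureManifest(spacing=10.0)

    def test_units_well_separated(self):
        manifest = sd.FixtureManifest(
            aromatic_pairs=[
                sd.AromaticPairSpec("HIS", "PHE", 3.8, 10.0, 70.0),
                sd.AromaticPairSpec("TYR", "TRP", 4.5, 30.0, 50.0),
            ],
            his_tag_runs=[5],
        )
        s, echo = sd.make_fixture_structure(manifest)
        mined = pm.mine(s)
        unique = {frozenset((p.ref_id, p.partner_id)) for p in mined}
        assert len(unique) == 2


EXPECTED_FRAGMENTS = {
    # (residue, scenario): (compound, atoms, charge, element counts)
    ("HIS", "HIE"): ("4-methylimidazole", 12, 0, {"C": 4, "N": 2, "H": 6}),
    ("HIS", "HID"): ("4-methylimidazole", 12, 0, {"C": 4, "N": 2, "H": 6}),
    ("HIS", "HIP"): ("4-methylimidazolium", 13, 1, {"C": 4, "N": 2, "H": 7}),
    ("PHE", None): ("toluene", 15, 0, {"C": 7, "H": 8}),
    ("TYR", None): ("4-methylphenol", 16, 0, {"C": 7, "O": 1, "H": 8}),
    ("TRP", None): ("3-methylindole", 19, 0, {"C": 9, "N": 1, "H": 9}),
    ("LYS", None): ("methylammonium", 8, 1, {"C": 1, "N": 1, "H": 6}),
    ("ARG", None): ("methylguanidinium", 13, 1, {"C": 2, "N": 3, "H": 8}),
}


class TestExtractQmFragment:
    @pytest.mark.parametrize("key", sorted(EXPECTED_FRAGMENTS, key=str))
    def test_formula_and_charge(self, key):
        name, scenario = key
        compound, n_atoms, charge, elements = EXPECTED_FRAGMENTS[key]
        frag = sd.extract_qm_fragment(sd.make_residue_template(name), scenario)
        assert frag.compound == compound
        assert len(frag.atoms) == n_atoms
        assert frag.net_charge == charge
        assert frag.element_counts() == elements

    def test_heavy_atoms_unmoved(self):
        rng = np.random.default_rng(61)
        res = transform(
            sd.make_residue_template("TRP"), random_rotation(rng), rng.uniform(-30, 30, 3)
        )
        frag = sd.extract_qm_fragment(res)
        by_name = {n: c for n, _, c in frag.atoms}
        for atom in res.heavy_atoms():
            if atom.name in by_name:
                assert np.linalg.norm(by_name[atom.name] - atom.coords) <= 1e-9

    def test_his_requires_scenario(self):
        with pytest.raises(ValueError, match="scenario"):
            sd.extract_qm_fragment(sd.make_residue_template("HIS"))

    def test_unsupported_residue(self):
        res = dataclasses.replace(sd.make_residue_template("PHE"), name="GLY")
        with pytest.raises(ValueError):
            sd.extract_qm_fragment(res)

    def test_cap_hydrogen_geometry(self):
        frag = sd.extract_qm_fragment(sd.make_residue_template("PHE"))
        cb = next(c for n, _, c in frag.atoms if n == "CB")
        cap_h = [c for n, el, c in frag.atoms if el == "H" and np.linalg.norm(c - cb) <= 1.2]
        assert len(cap_h) == 3
        for h in cap_h:
            assert np.linalg.norm(h - cb) == pytest.approx(sd.CAP_CH, abs=1e-6)


class TestWriteXyz:
    def test_toluene_atom_count_line(self, tmp_path):
        frag = sd.extract_qm_fragment(sd.make_residue_template("PHE"))
        path = sd.write_xyz(frag, tmp_path / "tol.xyz")
        assert path.read_text().splitlines()[0] == "15"

    def test_pair_concatenated_with_summed_charge(self, tmp_path):
        his = sd.extract_qm_fragment(sd.make_residue_template("HIS"), "HIP")
        lys = sd.extract_qm_fragment(sd.make_residue_template("LYS"))
        path = sd.write_xyz([his, lys], tmp_path / "pair.xyz")
        lines = path.read_text().splitlines()
        assert lines[0] == str(13 + 8)
        assert "charge=2" in lines[1]

    def test_read_back_round_trip(self, tmp_path):
        frag = sd.extract_qm_fragment(sd.make_residue_template("TYR"))
        path = sd.write_xyz(frag, tmp_path / "cresol.xyz")
        atoms, comment = sd.read_xyz(path)
        assert len(atoms) == len(frag.atoms)
        assert "charge=0" in comment
        for (el, coords), (_, el0, coords0) in zip(atoms, frag.atoms):
            assert el == el0
            np.testing.assert_allclose(coords, coords0, atol=1e-6)
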