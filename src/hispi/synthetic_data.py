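"""Ground-truth fixture generation.

Builds idealized residues, places residue pairs at exact target descriptor
values, assembles whole synthetic structures (His-tag runs, metal-bound His,
deuterated His with designed tautomers, designed H-bond micro-environments)
and extracts methyl-capped model-compound fragments for QM input.

Every placement is deterministic (zero-twist convention for the free
in-plane rotation) and round-trips through the descriptor code to within
1e-3 Å/degrees, which is what makes the rest of the pipeline testable
without any downloaded structures.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ring_geometry import (
    RING_ATOMS,
    add_ideal_hydrogens,
    aromatic_pair_geometry,
    build_ring,
    cation_pi_geometry,
    cation_site,
    _dihedral_h,
    _unit,
)
from .structure_io import Atom, Residue, Structure

__all__ = [
    "InfeasibleGeometryError",
    "QmFragment",
    "AromaticPairSpec",
    "CationPairSpec",
    "MicroEnvSpec",
    "FixtureManifest",
    "make_residue_template",
    "place_aromatic_pair",
    "place_cation_pair",
    "make_fixture_structure",
    "extract_qm_fragment",
    "write_xyz",
    "read_xyz",
]

RING_BOND_HIS = 1.37  # imidazole edge length, Å
RING_BOND_BENZENE = 1.39
CAP_CH = 1.09
CAP_NH = 1.01


class InfeasibleGeometryError(ValueError):
    """The requested target descriptor combination cannot be realized."""


# ---------------------------------------------------------------------------
# small rotation helpers
# ---------------------------------------------------------------------------

def _axis_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = _unit(np.asarray(axis, dtype=float))
    x, y, z = axis
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate π about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _axis_rotation(perp, math.pi)
    return _axis_rotation(v, math.atan2(s, c))


def _transform_residue(residue: Residue, rot: np.ndarray, shift: np.ndarray) -> Residue:
    atoms = [
        dataclasses.replace(a, coords=rot @ a.coords + shift) for a in residue.atoms
    ]
    return dataclasses.replace(residue, atoms=atoms)


def _translate_residue(residue: Residue, shift: np.ndarray) -> Residue:
    return _transform_residue(residue, np.eye(3), np.asarray(shift, dtype=float))


# ---------------------------------------------------------------------------
# idealized residue templates
# ---------------------------------------------------------------------------

def _regular_polygon(n: int, side: float) -> np.ndarray:
    radius = side / (2.0 * math.sin(math.pi / n))
    return np.array(
        [
            [radius * math.cos(2 * math.pi * i / n), radius * math.sin(2 * math.pi * i / n), 0.0]
            for i in range(n)
        ]
    )


def _his_sidechain() -> dict[str, np.ndarray]:
    # pentagon in bond order CG-ND1-CE1-NE2-CD2
    poly = _regular_polygon(5, RING_BOND_HIS)
    names = ("CG", "ND1", "CE1", "NE2", "CD2")
    coords = dict(zip(names, poly))
    coords["CB"] = coords["CG"] + 1.50 * _unit(coords["CG"])  # radially outward
    return coords


def _hexagon_sidechain(with_oh: bool) -> dict[str, np.ndarray]:
    poly = _regular_polygon(6, RING_BOND_BENZENE)
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    coords = dict(zip(names, poly))
    coords["CB"] = coords["CG"] + 1.50 * _unit(coords["CG"])
    if with_oh:
        coords["OH"] = coords["CZ"] + 1.36 * _unit(coords["CZ"])
    return coords


def _trp_sidechain() -> dict[str, np.ndarray]:
    # pyrrole ring in bond order CG-CD1-NE1-CE2-CD2, fused hexagon on CE2-CD2
    poly = _regular_polygon(5, RING_BOND_HIS)
    names = ("CG", "CD1", "NE1", "CE2", "CD2")
    coords = dict(zip(names, poly))
    a, b = coords["CD2"], coords["CE2"]
    side = float(np.linalg.norm(b - a))
    mid = (a + b) / 2.0
    perp = np.array([-(b - a)[1], (b - a)[0], 0.0])
    perp = _unit(perp)
    penta_center = np.zeros(3)
    if np.dot(perp, mid - penta_center) < 0:
        perp = -perp
    hex_center = mid + perp * side * math.sqrt(3.0) / 2.0
    # walk the hexagon from CD2 away from CE2
    rot_pos = _axis_rotation([0, 0, 1], math.pi / 3)
    rot_neg = _axis_rotation([0, 0, 1], -math.pi / 3)
    step = rot_pos if np.linalg.norm(rot_pos @ (a - hex_center) + hex_center - b) > 1e-6 else rot_neg
    v = a - hex_center
    for name in ("CE3", "CZ3", "CH2", "CZ2"):
        v = step @ v
        coords[name] = hex_center + v
    coords["CB"] = coords["CG"] + 1.50 * _unit(coords["CG"])  # radially outward
    return coords


def _lys_sidechain() -> dict[str, np.ndarray]:
    nz = np.zeros(3)
    ce = np.array([1.49, 0.0, 0.0])
    alpha = math.radians(70.53)
    cd = ce + 1.52 * np.array([math.cos(alpha), math.sin(alpha), 0.0])
    return {"NZ": nz, "CE": ce, "CD": cd}


def _arg_sidechain() -> dict[str, np.ndarray]:
    cz = np.zeros(3)
    ne = np.array([1.33, 0.0, 0.0])
    nh1 = 1.33 * np.array([math.cos(math.radians(120)), math.sin(math.radians(120)), 0.0])
    nh2 = 1.33 * np.array([math.cos(math.radians(240)), math.sin(math.radians(240)), 0.0])
    beta = math.radians(56.0)
    cd = ne + 1.46 * np.array([math.cos(beta), math.sin(beta), 0.0])
    return {"CD": cd, "NE": ne, "CZ": cz, "NH1": nh1, "NH2": nh2}


_VALID_SCENARIOS = {
    "HIS": {None, "HID", "HIE", "HIP", "aromatic_CH_only"},
    "PHE": {None, "aromatic_CH_only"},
    "TYR": {None, "aromatic_CH_only"},
    "TRP": {None, "aromatic_CH_only"},
    "LYS": {None, "lys_NZ3"},
    "ARG": {None, "arg_guanidinium"},
}

_ELEMENT_OF = {"N": "N", "O": "O", "C": "C"}


def make_residue_template(
    name: str, scenario: str | None = None, chain_id: str = "A", seq_number: int = 1
) -> Residue:
    """Idealized side-chain residue (planar ring centred at the origin in the
    z = 0 plane), with hydrogens added per ``scenario`` when given."""
    name = name.upper()
    if name not in _VALID_SCENARIOS:
        raise ValueError(f"unsupported residue {name}")
    if scenario not in _VALID_SCENARIOS[name]:
        raise ValueError(f"invalid scenario {scenario!r} for {name}")
    builders = {
        "HIS": _his_sidechain,
        "PHE": lambda: _hexagon_sidechain(with_oh=False),
        "TYR": lambda: _hexagon_sidechain(with_oh=True),
        "TRP": _trp_sidechain,
        "LYS": _lys_sidechain,
        "ARG": _arg_sidechain,
    }
    coords = builders[name]()
    atoms = [
        Atom(name=an, element=an[0] if an[0] in _ELEMENT_OF else "C", coords=c)
        for an, c in coords.items()
    ]
    residue = Residue(chain_id=chain_id, seq_number=seq_number, name=name, atoms=atoms)
    if scenario is not None:
        residue = add_ideal_hydrogens(residue, scenario)
    return residue


# ---------------------------------------------------------------------------
# exact-target pair placement
# ---------------------------------------------------------------------------

def _clamp(x: float, lo: float = -1.0, hi: float = 1.0) -> float:
    return min(hi, max(lo, x))


def _solve_partner_normal(
    D: float, P: float, t2: float, t1: float | None
) -> tuple[float, np.ndarray]:
    """Find an elevation t1 and partner normal realizing (D, P, Tθ2[, Tθ1]).

    The reference ring sits in z = 0 with normal ẑ; the partner centroid is
    placed at elevation t1 in the xz-plane and its normal at polar angle P
    with azimuth φ (zero-twist: the smallest |φ| that satisfies Tθ2).
    """
    sinP, cosP = math.sin(math.radians(P)), math.cos(math.radians(P))
    sin2 = math.sin(math.radians(t2))

    def phi_for(t1v: float) -> float | None:
        sin1, cos1 = math.sin(math.radians(t1v)), math.cos(math.radians(t1v))
        if sinP * cos1 < 1e-12:
            # normal fixed up to sign (P=0 or centroid on the axis)
            achieved = abs(sin1 * cosP) if sinP < 1e-12 else abs(cosP)
            return 0.0 if abs(achieved - sin2) <= 1e-9 else None
        for target in (sin2, -sin2):
            c = (target - sin1 * cosP) / (cos1 * sinP)
            if abs(c) <= 1.0 + 1e-12:
                return math.degrees(math.acos(_clamp(c)))
        return None

    candidates: list[float]
    if t1 is not None:
        candidates = [t1]
    else:
        exact = [t2, t2 + P, t2 - P, P - t2, 90.0 - P, 90.0]
        grid = list(np.linspace(0.0, 90.0, 181))
        candidates = [t for t in exact + grid if -1e-9 <= t <= 90.0 + 1e-9]
    for t1v in candidates:
        t1v = min(90.0, max(0.0, t1v))
        phi = phi_for(t1v)
        if phi is not None:
            phi_rad = math.radians(phi)
            normal = np.array(
                [sinP * math.cos(phi_rad), sinP * math.sin(phi_rad), cosP]
            )
            return t1v, normal
    raise InfeasibleGeometryError(
        f"no pose realizes D={D}, P={P}, T_theta2={t2}, T_theta1={t1}"
    )


def place_aromatic_pair(
    template_ref: Residue,
    template_partner: Residue,
    D: float,
    P: float,
    T_theta2: float,
    T_theta1: float | None = None,
) -> Structure:
    """Two-residue structure whose recomputed descriptors match the targets
    (within 1e-3).  The reference ring sits in the z = 0 plane at the origin.

    ``T_theta1`` may be left free (``None``); it is then fixed
    deterministically by the solver.  With P = 0 the two elevations are
    geometrically forced to coincide.
    """
    if not D > 2.0:
        raise InfeasibleGeometryError("D must exceed 2 Å")
    for a in (P, T_theta2) + (() if T_theta1 is None else (T_theta1,)):
        if not 0.0 <= a <= 90.0:
            raise InfeasibleGeometryError(f"angle {a} outside [0, 90]")

    ref = dataclasses.replace(template_ref, chain_id="A", seq_number=1)
    # anchor both ring centroids (the Trp indole centroid is off the template
    # origin) — reference at the origin, partner at the target elevation
    ref = _translate_residue(ref, -build_ring(ref).centroid)
    t1v, partner_normal = _solve_partner_normal(D, P, T_theta2, T_theta1)
    t1_rad = math.radians(t1v)
    centroid_b = D * np.array([math.cos(t1_rad), 0.0, math.sin(t1_rad)])
    rot = _rotation_between(np.array([0.0, 0.0, 1.0]), partner_normal)
    partner = dataclasses.replace(template_partner, chain_id="A", seq_number=2)
    partner = _translate_residue(partner, -build_ring(partner).centroid)
    partner = _transform_residue(partner, rot, centroid_b)
    structure = Structure(id="placed_pair", residues=[ref, partner])

    geom = aromatic_pair_geometry(build_ring(ref), build_ring(partner))
    checks = [(geom.D, D), (geom.P, P), (geom.T_theta2, T_theta2)]
    if T_theta1 is not None:
        checks.append((geom.T_theta1, T_theta1))
    if any(abs(got - want) > 1e-3 for got, want in checks):
        raise InfeasibleGeometryError(
            f"target (D={D}, P={P}, Tθ2={T_theta2}, Tθ1={T_theta1}) "
            f"not reproduced: got (D={geom.D:.4f}, P={geom.P:.4f}, "
            f"Tθ2={geom.T_theta2:.4f}, Tθ1={geom.T_theta1:.4f})"
        )
    return structure


def place_cation_pair(
    ring_template: Residue,
    cation_template: Residue,
    D: float,
    theta1: float,
    theta2: float | None = None,
    prefer_nitrogen: str = "NE2",
) -> Structure:
    """Two-residue structure realizing the cation–π targets (within 1e-3).

    The π ring sits in z = 0 at the origin; the cation center atom is placed
    at distance ``D`` and axis angle ``theta1``.  ``theta2`` (plane angle) is
    honored for Arg and His cations and rejected for Lys, which has no plane.
    For a His cation the ring is oriented so that ``prefer_nitrogen`` is the
    nitrogen nearer the π centroid.
    """
    if not D > 2.0:
        raise InfeasibleGeometryError("D must exceed 2 Å")
    if not 0.0 <= theta1 <= 90.0 or (theta2 is not None and not 0.0 <= theta2 <= 90.0):
        raise InfeasibleGeometryError("angles must lie in [0, 90]")
    cat_name = cation_template.name
    if cat_name == "LYS" and theta2 is not None:
        raise InfeasibleGeometryError("Lys defines no cation plane; theta2 is not realizable")

    ring_res = dataclasses.replace(ring_template, chain_id="A", seq_number=1)
    ring_res = _translate_residue(ring_res, -build_ring(ring_res).centroid)
    t1 = math.radians(theta1)
    pos = D * np.array([math.sin(t1), 0.0, math.cos(t1)])
    p_hat = _unit(pos)

    cat = dataclasses.replace(cation_template, chain_id="A", seq_number=2)
    if cat_name == "LYS":
        nz, ce = cat.get_atom("NZ").coords, cat.get_atom("CE").coords
        rot = _rotation_between(nz - ce if np.linalg.norm(nz - ce) else [0, 0, 1], p_hat)
        # NZ on the target point, tail pointing away from the ring
        cat = _transform_residue(cat, rot, np.zeros(3))
        cat = _translate_residue(cat, pos - cat.get_atom("NZ").coords)
        center_name = "NZ"
    else:
        t2 = 0.0 if theta2 is None else theta2
        q = np.array([0.0, 0.0, 1.0]) - np.dot([0.0, 0.0, 1.0], p_hat) * p_hat
        q_hat = _unit(q) if np.linalg.norm(q) > 1e-9 else np.array([1.0, 0.0, 0.0])
        m = math.cos(math.radians(t2)) * p_hat + math.sin(math.radians(t2)) * q_hat
        rot = _rotation_between(np.array([0.0, 0.0, 1.0]), m)
        cat = _transform_residue(cat, rot, np.zeros(3))
        center_name = "CZ" if cat_name == "ARG" else prefer_nitrogen
        cat = _translate_residue(cat, pos - cat.get_atom(center_name).coords)
        if cat_name == "HIS":
            cat = _orient_his_cation(cat, m, pos, prefer_nitrogen)

    structure = Structure(id="placed_cation_pair", residues=[ring_res, cat])
    ring = build_ring(ring_res)
    site = cation_site(cat, partner_centroid=ring.centroid)
    geom = cation_pi_geometry(ring, site)
    checks = [(geom.D, D), (geom.theta1, theta1)]
    if theta2 is not None and geom.theta2 is not None:
        checks.append((geom.theta2, theta2))
    if any(abs(got - want) > 1e-3 for got, want in checks):
        raise InfeasibleGeometryError(
            f"cation targets (D={D}, θ1={theta1}, θ2={theta2}) not reproduced: "
            f"got (D={geom.D:.4f}, θ1={geom.theta1:.4f}, θ2={geom.theta2})"
        )
    if cat_name == "HIS" and site.chosen_nitrogen != prefer_nitrogen:
        raise InfeasibleGeometryError(
            f"could not orient His cation with {prefer_nitrogen} nearest the centroid"
        )
    return structure


def _orient_his_cation(
    cat: Residue, plane_normal: np.ndarray, anchor: np.ndarray, prefer: str
) -> Residue:
    """Spin the His ring about its plane normal (through the anchored
    nitrogen) so the preferred nitrogen stays nearest the π centroid."""
    other = "ND1" if prefer == "NE2" else "NE2"
    best, best_score = cat, -math.inf
    for step in range(12):
        rot = _axis_rotation(plane_normal, math.radians(30.0 * step))
        spun = _transform_residue(cat, rot, np.zeros(3))
        spun = _translate_residue(spun, anchor - spun.get_atom(prefer).coords)
        score = float(np.linalg.norm(spun.get_atom(other).coords))  # centroid at origin
        if score > best_score:
            best, best_score = spun, score
    return best


# ---------------------------------------------------------------------------
# whole-structure fixtures
# ---------------------------------------------------------------------------

@dataclass
class AromaticPairSpec:
    ref_name: str
    partner_name: str
    D: float
    P: float
    T_theta2: float
    T_theta1: float | None = None
    ref_scenario: str | None = None
    partner_scenario: str | None = None
    expected_labels: tuple[str, ...] = ()


@dataclass
class CationPairSpec:
    pi_name: str
    cation_name: str
    D: float
    theta1: float
    theta2: float | None = None
    expected_labels: tuple[str, ...] = ()


@dataclass
class MicroEnvSpec:
    """Designed H-bond micro-environment around one His.

    kinds: ``acceptor_nd1`` (→ neutral/ε0), ``double_donor`` (→ positive),
    ``isolated`` (→ undetermined), ``metal`` (→ neutral_metal),
    ``single_hbond`` (designed-ambiguous → undetermined).
    """

    kind: str
    expected_state: str = ""
    expected_tautomer: str | None = None

    _EXPECT = {
        "acceptor_nd1": ("neutral", "epsilon0"),
        "double_donor": ("positive", None),
        "isolated": ("undetermined", None),
        "metal": ("neutral_metal", None),
        "single_hbond": ("undetermined", None),
    }

    def __post_init__(self):
        if self.kind not in self._EXPECT:
            raise ValueError(f"unknown micro-environment kind {self.kind!r}")
        if not self.expected_state:
            self.expected_state, self.expected_tautomer = self._EXPECT[self.kind]


@dataclass
class FixtureManifest:
    aromatic_pairs: list[AromaticPairSpec] = field(default_factory=list)
    cation_pairs: list[CationPairSpec] = field(default_factory=list)
    his_tag_runs: list[int] = field(default_factory=list)
    metal_his: list[tuple[str, float]] = field(default_factory=list)  # (element, N–metal distance)
    deuterated: dict[str, int] = field(default_factory=dict)  # tautomer → count (+ "undeuterated")
    microenvironments: list[MicroEnvSpec] = field(default_factory=list)
    waters: int = 0
    spacing: float = 30.0
    structure_id: str = "fixture"

    def __post_init__(self):
        if self.spacing < 15.0:
            raise ValueError("unit spacing below 15 Å risks cross-unit pairs")


def _grid_offsets(n: int, spacing: float):
    # units line up along x; runs/waters extend along y only, so an x-step of
    # spacing + 10 Å guarantees ≥ spacing between any two units' atoms
    step = spacing + 10.0
    for i in range(n):
        yield np.array([i * step, 0.0, 0.0])


def _deuterate_ring_nh(residue: Residue) -> Residue:
    """Convert ring N–H hydrogens (HD1/HE2) into deuterium (DD1/DE2)."""
    atoms = []
    for a in residue.atoms:
        if a.name in ("HD1", "HE2"):
            atoms.append(
                dataclasses.replace(a, name="D" + a.name[1:], element="D", is_deuterium=True)
            )
        else:
            atoms.append(a)
    return dataclasses.replace(residue, atoms=atoms)


def _water(chain: str, seq: int, o_pos: np.ndarray, h_targets: list[np.ndarray]) -> Residue:
    """Water with hydrogens aimed at ``h_targets`` (0–2 of them)."""
    atoms = [Atom(name="O", element="O", coords=o_pos)]
    for i, target in enumerate(h_targets, start=1):
        atoms.append(
            Atom(name=f"H{i}", element="H", coords=o_pos + 0.96 * _unit(target - o_pos))
        )
    return Residue(chain_id=chain, seq_number=seq, name="HOH", atoms=atoms, is_hetero=True)


def _bisector_direction(residue: Residue, atom_name: str) -> np.ndarray:
    """In-plane external-bisector direction off a His ring nitrogen."""
    from .ring_geometry import RING_BONDS

    x = residue.get_atom(atom_name).coords
    ring = build_ring(residue)
    direction = np.zeros(3)
    for a, b in RING_BONDS[residue.name]:
        if atom_name in (a, b):
            nb = b if a == atom_name else a
            direction -= _unit(residue.get_atom(nb).coords - x)
    direction -= np.dot(direction, ring.normal) * ring.normal
    return _unit(direction)


def make_fixture_structure(manifest: FixtureManifest) -> tuple[Structure, dict]:
    """Assemble one structure embedding every designed element.

    Units are laid out on a grid with ≥ ``manifest.spacing`` Å separation so
    designed pairs are the only mined pairs.  Returns (structure, manifest
    echo) where the echo maps designed elements to their residue ids and
    expected pipeline outputs.
    """
    residues: list[Residue] = []
    hetero: list[Residue] = []
    echo: dict = {
        "pairs": [],
        "his_tag_ids": [],
        "metal_his_ids": [],
        "tautomers": {},
        "microenvironments": [],
    }
    n_units = (
        len(manifest.aromatic_pairs)
        + len(manifest.cation_pairs)
        + len(manifest.his_tag_runs)
        + len(manifest.metal_his)
        + sum(manifest.deuterated.values())
        + len(manifest.microenvironments)
        + manifest.waters
    )
    offsets = list(_grid_offsets(n_units, manifest.spacing))
    unit = 0
    seq = 1
    water_seq = 1000

    def next_offset():
        nonlocal unit
        off = offsets[unit]
        unit += 1
        return off

    for spec in manifest.aromatic_pairs:
        off = next_offset()
        t_ref = make_residue_template(spec.ref_name, spec.ref_scenario)
        t_par = make_residue_template(spec.partner_name, spec.partner_scenario)
        placed = place_aromatic_pair(t_ref, t_par, spec.D, spec.P, spec.T_theta2, spec.T_theta1)
        ref, par = placed.residues
        ref = dataclasses.replace(_translate_residue(ref, off), seq_number=seq)
        par = dataclasses.replace(_translate_residue(par, off), seq_number=seq + 1)
        residues += [ref, par]
        echo["pairs"].append(
            {"family": "aromatic", "ref_id": ref.rid, "partner_id": par.rid, "spec": spec}
        )
        seq += 10

    for spec in manifest.cation_pairs:
        off = next_offset()
        t_pi = make_residue_template(spec.pi_name)
        t_cat = make_residue_template(spec.cation_name)
        placed = place_cation_pair(t_pi, t_cat, spec.D, spec.theta1, spec.theta2)
        pi_res, cat_res = placed.residues
        pi_res = dataclasses.replace(_translate_residue(pi_res, off), seq_number=seq)
        cat_res = dataclasses.replace(_translate_residue(cat_res, off), seq_number=seq + 1)
        residues += [pi_res, cat_res]
        echo["pairs"].append(
            {
                "family": "cation_pi",
                "pi_id": pi_res.rid,
                "cation_id": cat_res.rid,
                "spec": spec,
            }
        )
        seq += 10

    for run_length in manifest.his_tag_runs:
        off = next_offset()
        ids = []
        for j in range(run_length):
            his = make_residue_template("HIS")
            # 10 Å spacing keeps run members beyond both mining cutoffs
            his = dataclasses.replace(
                _translate_residue(his, off + np.array([0.0, 10.0 * j, 0.0])),
                seq_number=seq + j,
            )
            residues.append(his)
            ids.append(his.rid)
        echo["his_tag_ids"].append(ids)
        seq += run_length + 9

    for element, distance in manifest.metal_his:
        off = next_offset()
        his = dataclasses.replace(_translate_residue(make_residue_template("HIS"), off), seq_number=seq)
        direction = _bisector_direction(his, "NE2")
        metal_pos = his.get_atom("NE2").coords + distance * direction
        hetero.append(
            Residue(
                chain_id="A",
                seq_number=water_seq,
                name=element.upper(),
                atoms=[Atom(name=element.upper(), element=element.upper(), coords=metal_pos)],
                is_hetero=True,
            )
        )
        residues.append(his)
        echo["metal_his_ids"].append(his.rid)
        seq += 10
        water_seq += 1

    scenario_of = {"epsilon0": "HIE", "delta0": "HID", "positive": "HIP", "undeuterated": None}
    for tautomer, count in manifest.deuterated.items():
        if tautomer not in scenario_of:
            raise ValueError(f"unknown tautomer {tautomer!r}")
        for _ in range(count):
            off = next_offset()
            scen = scenario_of[tautomer]
            his = make_residue_template("HIS", scen)
            if scen is not None:
                his = _deuterate_ring_nh(his)
            his = dataclasses.replace(_translate_residue(his, off), seq_number=seq)
            residues.append(his)
            echo["tautomers"][his.rid] = (
                tautomer if tautomer != "undeuterated" else "not_determinable"
            )
            seq += 10

    for spec in manifest.microenvironments:
        off = next_offset()
        his = dataclasses.replace(_translate_residue(make_residue_template("HIS"), off), seq_number=seq)
        residues.append(his)
        entry = {"his_id": his.rid, "spec": spec}
        nd1 = his.get_atom("ND1").coords
        ne2 = his.get_atom("NE2").coords
        dir_nd1 = _bisector_direction(his, "ND1")
        dir_ne2 = _bisector_direction(his, "NE2")
        away = off + np.array([0.0, 0.0, 50.0])  # aim waters' own H far away
        if spec.kind == "acceptor_nd1":
            o1 = nd1 + 2.8 * dir_nd1
            hetero.append(_water("A", water_seq, o1, [nd1, away]))
            water_seq += 1
            o2 = ne2 + 2.9 * dir_ne2
            hetero.append(_water("A", water_seq, o2, [o2 + 2.0 * dir_ne2, away]))
            water_seq += 1
        elif spec.kind == "double_donor":
            for n_pos, direction in ((nd1, dir_nd1), (ne2, dir_ne2)):
                o = n_pos + 2.9 * direction
                hetero.append(_water("A", water_seq, o, [o + 2.0 * direction, away]))
                water_seq += 1
        elif spec.kind == "metal":
            metal_pos = ne2 + 2.1 * dir_ne2
            hetero.append(
                Residue(
                    chain_id="A",
                    seq_number=water_seq,
                    name="ZN",
                    atoms=[Atom(name="ZN", element="ZN", coords=metal_pos)],
                    is_hetero=True,
                )
            )
            water_seq += 1
        elif spec.kind == "single_hbond":
            o = ne2 + 2.9 * dir_ne2
            hetero.append(_water("A", water_seq, o, [o + 2.0 * dir_ne2, away]))
            water_seq += 1
        # "isolated": nothing added
        echo["microenvironments"].append(entry)
        seq += 10

    for _ in range(manifest.waters):
        off = next_offset()
        hetero.append(_water("A", water_seq, off, []))
        water_seq += 1

    method = "neutron" if manifest.deuterated else "xray"
    structure = Structure(
        id=manifest.structure_id,
        residues=residues,
        hetero=hetero,
        resolution=1.5,
        r_factor=0.15,
        method=method,
    )
    expected_pair_count = len(manifest.aromatic_pairs) + len(manifest.cation_pairs)
    echo["expected_mined_pair_count"] = expected_pair_count
    return structure, echo


# ---------------------------------------------------------------------------
# QM fragment extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QmFragment:
    source_residue: str
    compound: str
    atoms: tuple[tuple[str, str, np.ndarray], ...]  # (name, element, coords)
    net_charge: int

    def element_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, el, _ in self.atoms:
            out[el] = out.get(el, 0) + 1
        return out


_FRAGMENT_PLAN = {
    # residue -> (heavy atoms kept, cap carbon, cap anchor, dihedral ref, H scenario)
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2", "CB"), "CB", "CG", "ND1", None),
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "CB"), "CB", "CG", "CD1", "aromatic_CH_only"),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH", "CB"), "CB", "CG", "CD1", "aromatic_CH_only"),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2", "CB"),
        "CB", "CG", "CD1", "aromatic_CH_only",
    ),
    "LYS": (("CE", "NZ"), "CE", "NZ", None, "lys_NZ3"),
    "ARG": (("CD", "NE", "CZ", "NH1", "NH2"), "CD", "NE", "CZ", "arg_guanidinium"),
}

_COMPOUND = {
    ("HIS", "HIE"): ("4-methylimidazole", 0),
    ("HIS", "HID"): ("4-methylimidazole", 0),
    ("HIS", "HIP"): ("4-methylimidazolium", 1),
    ("PHE", None): ("toluene", 0),
    ("TYR", None): ("4-methylphenol", 0),
    ("TRP", None): ("3-methylindole", 0),
    ("LYS", None): ("methylammonium", 1),
    ("ARG", None): ("methylguanidinium", 1),
}


def extract_qm_fragment(residue: Residue, scenario: str | None = None) -> QmFragment:
    """Methyl-capped model compound for a side chain.

    Keeps the functional group plus exactly one extra carbon (converted into
    a methyl cap); retained heavy atoms keep their source coordinates
    bit-for-bit, cap and ring hydrogens are placed at ideal geometry.
    """
    name = residue.name
    if name not in _FRAGMENT_PLAN:
        raise ValueError(f"unsupported residue {name} for fragment extraction")
    if name == "HIS":
        if scenario not in ("HIE", "HID", "HIP"):
            raise ValueError("His fragments require scenario HIE, HID or HIP")
        compound, charge = _COMPOUND[("HIS", scenario)]
        h_scenario = scenario
    else:
        compound, charge = _COMPOUND[(name, None)]
        h_scenario = _FRAGMENT_PLAN[name][4]

    heavy_names, cap, anchor, dihedral_ref, _ = _FRAGMENT_PLAN[name]
    missing = [n for n in heavy_names if residue.get_atom(n) is None]
    if missing:
        raise ValueError(f"{residue.rid}: missing heavy atoms {missing}")

    atoms: list[tuple[str, str, np.ndarray]] = [
        (n, residue.get_atom(n).element.upper(), residue.get_atom(n).coords.copy())
        for n in heavy_names
    ]

    # polar/ring hydrogens at ideal positions
    with_h = add_ideal_hydrogens(residue, h_scenario)
    retained = set(heavy_names)
    heavy_coords = {n: residue.get_atom(n).coords for n in retained}
    for h in with_h.hydrogens():
        parents = [
            n for n, c in heavy_coords.items() if np.linalg.norm(h.coords - c) <= 1.2
        ]
        if parents:
            atoms.append((h.name, "H", h.coords.copy()))

    # methyl cap hydrogens
    cap_atom = residue.get_atom(cap)
    anchor_atom = residue.get_atom(anchor)
    if dihedral_ref is not None:
        ref_coords = residue.get_atom(dihedral_ref).coords
    else:  # Lys: stagger against the first ammonium hydrogen
        ref_coords = next(
            a.coords
            for a in with_h.hydrogens()
            if np.linalg.norm(a.coords - residue.get_atom("NZ").coords) <= 1.2
        )
    for i, dihedral in enumerate((60.0, 180.0, 300.0), start=1):
        pos = _dihedral_h(
            cap_atom.coords, anchor_atom.coords, ref_coords, CAP_CH, 109.47, dihedral
        )
        atoms.append((f"H{cap}{i}", "H", pos))

    return QmFragment(
        source_residue=residue.rid,
        compound=compound,
        atoms=tuple(atoms),
        net_charge=charge,
    )


def write_xyz(fragment_or_pair, path: str | Path) -> Path:
    """Standard XYZ output; a sequence of fragments is concatenated into one
    block with the summed net charge in the comment line."""
    path = Path(path)
    fragments = (
        [fragment_or_pair] if isinstance(fragment_or_pair, QmFragment) else list(fragment_or_pair)
    )
    atoms = [a for f in fragments for a in f.atoms]
    charge = sum(f.net_charge for f in fragments)
    compounds = "+".join(f.compound for f in fragments)
    sources = "+".join(f.source_residue for f in fragments)
    lines = [str(len(atoms)), f"charge={charge} compound={compounds} source={sources}"]
    for _, element, coords in atoms:
        x, y, z = coords
        lines.append(f"{element:<2} {x:14.6f} {y:14.6f} {z:14.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_xyz(path: str | Path) -> tuple[list[tuple[str, np.ndarray]], str]:
    """Read back an XYZ file → ([(element, coords)], comment line)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    comment = lines[1]
    atoms = []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        atoms.append((parts[0], np.array([float(v) for v in parts[1:4]])))
    return atoms, comment
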