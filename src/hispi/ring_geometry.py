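"""Aromatic ring and cation-site geometry.

Builds least-squares ring planes and computes the pairwise descriptors used
throughout the analysis:

* ring–ring: centroid distance ``D``, inter-normal angle ``P`` and the two
  elevation angles ``T_theta1`` / ``T_theta2`` (all angles folded to [0, 90]);
* cation–ring: cation-to-centroid distance ``D``, the axis angle ``theta1``
  and, when the cation carries a plane (Arg guanidinium, protonated His
  ring), the plane angle ``theta2``.

Also provides idealized hydrogen placement for the protonation scenarios
(ND1-, NE2- or doubly protonated His; aromatic C–H; Lys ammonium; Arg
guanidinium), which supports CH–π / H-bond classification on structures
without experimental hydrogens.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .structure_io import Atom, Residue

__all__ = [
    "RING_ATOMS",
    "RING_BONDS",
    "AromaticRing",
    "CationSite",
    "AromaticPairGeometry",
    "CationPiGeometry",
    "RingBuildError",
    "fold90",
    "build_ring",
    "aromatic_pair_geometry",
    "cation_pi_geometry",
    "his_plus_cation_site",
    "cation_site",
    "add_ideal_hydrogens",
    "SCENARIOS",
]

# Ordered ring-atom names per residue.  Trp uses the full 9-atom indole by
# default; pass ring_spec=RING_ATOMS_TRP6 for the 6-membered ring only.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "HIS": ("CG", "ND1", "CE1", "NE2", "CD2"),
    "PHE": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
    "TYR": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"),
}

RING_ATOMS_TRP6: dict[str, tuple[str, ...]] = {
    **RING_ATOMS,
    "TRP": ("CD2", "CE3", "CZ3", "CH2", "CZ2", "CE2"),
}

# Ring bond graph (used for external-bisector hydrogen placement).
RING_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "HIS": (("CG", "ND1"), ("ND1", "CE1"), ("CE1", "NE2"), ("NE2", "CD2"), ("CD2", "CG")),
    "PHE": (("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")),
    "TYR": (("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")),
    "TRP": (
        ("CG", "CD1"), ("CD1", "NE1"), ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
        ("CE2", "CZ2"), ("CZ2", "CH2"), ("CH2", "CZ3"), ("CZ3", "CE3"), ("CE3", "CD2"),
    ),
}

AROMATIC_RESIDUES = ("HIS", "PHE", "TYR", "TRP")
CATION_RESIDUES = ("LYS", "ARG", "HIS")

NH_LENGTH = 1.01
CH_LENGTH = 1.08
OH_LENGTH = 0.96

SCENARIOS = ("HID", "HIE", "HIP", "aromatic_CH_only", "lys_NZ3", "arg_guanidinium")


class RingBuildError(ValueError):
    """Missing ring atoms or an unacceptably distorted (non-planar) ring."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(_unit(u), _unit(v)))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def fold90(angle_deg: float) -> float:
    """Fold an angle in degrees to [0, 90] (``min(a, 180 - a)`` after mod 180)."""
    a = angle_deg % 180.0
    return min(a, 180.0 - a)


@dataclass(frozen=True)
class AromaticRing:
    residue_id: str
    residue_name: str
    atom_names: tuple[str, ...]
    coords: np.ndarray  # (n, 3) ring atom coordinates
    centroid: np.ndarray
    normal: np.ndarray
    planarity_rmsd: float


@dataclass(frozen=True)
class CationSite:
    residue_id: str
    residue_name: str
    center_name: str
    center: np.ndarray
    plane_normal: np.ndarray | None = None  # None for Lys (no plane defined)
    chosen_nitrogen: str | None = None  # set only for a protonated-His cation


@dataclass(frozen=True)
class AromaticPairGeometry:
    D: float
    P: float
    T_theta1: float  # elevation of partner centroid above the reference ring plane
    T_theta2: float  # elevation of reference centroid above the partner ring plane

    def __post_init__(self):
        if not self.D > 0:
            raise ValueError("D must be positive")
        for a in (self.P, self.T_theta1, self.T_theta2):
            if not -1e-9 <= a <= 90.0 + 1e-9:
                raise ValueError(f"angle {a} outside [0, 90]")


@dataclass(frozen=True)
class CationPiGeometry:
    D: float
    theta1: float
    theta2: float | None = None
    chosen_nitrogen: str | None = None

    def __post_init__(self):
        if not self.D > 0:
            raise ValueError("D must be positive")


def build_ring(
    residue: Residue,
    ring_spec: dict[str, tuple[str, ...]] | None = None,
    planarity_tol: float = 0.1,
) -> AromaticRing:
    """Least-squares ring plane for an aromatic residue.

    The centroid is the arithmetic mean of the ring atoms; the normal is the
    unit singular vector of smallest variance (sign unspecified — every
    downstream angle is folded to [0, 90]).

    Raises :class:`RingBuildError` if a ring atom is missing or the
    out-of-plane RMSD exceeds ``planarity_tol``.
    """
    spec = ring_spec or RING_ATOMS
    names = spec.get(residue.name)
    if names is None:
        raise RingBuildError(f"{residue.rid}: no ring definition for {residue.name}")
    coords = []
    for name in names:
        atom = residue.get_atom(name)
        if atom is None:
            raise RingBuildError(f"{residue.rid}: missing ring atom {name}")
        coords.append(atom.coords)
    X = np.asarray(coords, dtype=float)
    centroid = X.mean(axis=0)
    _, _, vt = np.linalg.svd(X - centroid)
    normal = _unit(vt[2])
    rmsd = float(np.sqrt(np.mean(((X - centroid) @ normal) ** 2)))
    if rmsd > planarity_tol:
        raise RingBuildError(
            f"{residue.rid}: ring planarity RMSD {rmsd:.3f} Å exceeds {planarity_tol} Å"
        )
    return AromaticRing(
        residue_id=residue.rid,
        residue_name=residue.name,
        atom_names=tuple(names),
        coords=X,
        centroid=centroid,
        normal=normal,
        planarity_rmsd=rmsd,
    )


def aromatic_pair_geometry(
    ring_ref: AromaticRing, ring_partner: AromaticRing
) -> AromaticPairGeometry:
    """Descriptors D / P / Tθ1 / Tθ2 for a ring–ring pair.

    ``ring_ref`` is the reference (His, when exactly one member is His).
    Tθ1 elevates the partner centroid above the reference plane; Tθ2
    elevates the reference centroid above the partner plane.
    """
    dvec = ring_partner.centroid - ring_ref.centroid
    D = float(np.linalg.norm(dvec))
    if D < 0.1:
        raise ValueError("coincident ring centroids")
    P = fold90(_angle_deg(ring_ref.normal, ring_partner.normal))
    s1 = min(1.0, abs(float(np.dot(dvec, ring_ref.normal))) / D)
    s2 = min(1.0, abs(float(np.dot(-dvec, ring_partner.normal))) / D)
    return AromaticPairGeometry(
        D=D,
        P=P,
        T_theta1=math.degrees(math.asin(s1)),
        T_theta2=math.degrees(math.asin(s2)),
    )


def cation_pi_geometry(pi_ring: AromaticRing, cation: CationSite) -> CationPiGeometry:
    """Descriptors D / θ1 (/ θ2) for a cation over a π ring."""
    dvec = cation.center - pi_ring.centroid
    D = float(np.linalg.norm(dvec))
    if D < 0.1:
        raise ValueError("cation atom coincident with ring centroid")
    theta1 = fold90(_angle_deg(pi_ring.normal, dvec))
    theta2 = None
    if cation.plane_normal is not None:
        theta2 = fold90(_angle_deg(cation.plane_normal, dvec))
    return CationPiGeometry(
        D=D, theta1=theta1, theta2=theta2, chosen_nitrogen=cation.chosen_nitrogen
    )


def his_plus_cation_site(his_residue: Residue, partner_centroid: np.ndarray) -> CationSite:
    """Cation site for a (putatively protonated) His.

    The charged center is whichever ring nitrogen (NE2/ND1) lies closer to
    the partner π centroid; exact ties choose NE2.
    """
    ne2 = his_residue.get_atom("NE2")
    nd1 = his_residue.get_atom("ND1")
    if ne2 is None or nd1 is None:
        raise RingBuildError(f"{his_residue.rid}: missing ring nitrogen")
    partner_centroid = np.asarray(partner_centroid, dtype=float)
    d_ne2 = np.linalg.norm(ne2.coords - partner_centroid)
    d_nd1 = np.linalg.norm(nd1.coords - partner_centroid)
    chosen = ne2 if d_ne2 <= d_nd1 else nd1
    ring = build_ring(his_residue)
    return CationSite(
        residue_id=his_residue.rid,
        residue_name="HIS",
        center_name=chosen.name,
        center=chosen.coords,
        plane_normal=ring.normal,
        chosen_nitrogen=chosen.name,
    )


def cation_site(residue: Residue, partner_centroid: np.ndarray | None = None) -> CationSite:
    """Cation site for Lys (NZ, no plane), Arg (CZ, guanidinium plane) or His."""
    if residue.name == "LYS":
        nz = residue.get_atom("NZ")
        if nz is None:
            raise RingBuildError(f"{residue.rid}: missing NZ")
        return CationSite(residue.rid, "LYS", "NZ", nz.coords)
    if residue.name == "ARG":
        names = ("NE", "CZ", "NH1", "NH2")
        coords = []
        for n in names:
            a = residue.get_atom(n)
            if a is None:
                raise RingBuildError(f"{residue.rid}: missing guanidinium atom {n}")
            coords.append(a.coords)
        X = np.asarray(coords)
        c = X.mean(axis=0)
        _, _, vt = np.linalg.svd(X - c)
        cz = residue.get_atom("CZ")
        return CationSite(residue.rid, "ARG", "CZ", cz.coords, plane_normal=_unit(vt[2]))
    if residue.name == "HIS":
        if partner_centroid is None:
            raise ValueError("His cation site requires the partner centroid")
        return his_plus_cation_site(residue, partner_centroid)
    raise ValueError(f"{residue.name} is not a supported cation residue")


# ---------------------------------------------------------------------------
# Idealized hydrogen placement
# ---------------------------------------------------------------------------

def _ring_neighbors(resname: str, atom: str) -> list[str]:
    out = []
    for a, b in RING_BONDS[resname]:
        if a == atom:
            out.append(b)
        elif b == atom:
            out.append(a)
    return out


def _bisector_h(
    residue: Residue, heavy: str, neighbors: list[str], length: float, normal: np.ndarray
) -> np.ndarray:
    """H along the in-plane external bisector of ``heavy``'s neighbors."""
    x = residue.get_atom(heavy).coords
    direction = np.zeros(3)
    for nb in neighbors:
        direction -= _unit(residue.get_atom(nb).coords - x)
    direction = direction - np.dot(direction, normal) * normal  # keep in plane
    return x + length * _unit(direction)


def _dihedral_h(
    center: np.ndarray,
    axis_from: np.ndarray,
    ref: np.ndarray,
    length: float,
    bond_angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place H bonded to ``center`` given the ``axis_from–center`` bond, a
    reference substituent on ``axis_from`` and target bond angle/dihedral."""
    u = _unit(center - axis_from)
    r = ref - axis_from
    r = r - np.dot(r, u) * u
    r = _unit(r)
    w = np.cross(u, r)
    beta = math.radians(180.0 - bond_angle_deg)
    phi = math.radians(dihedral_deg)
    direction = math.cos(beta) * u + math.sin(beta) * (math.cos(phi) * r + math.sin(phi) * w)
    return center + length * direction


def _strip_hydrogens_on(residue: Residue, heavy_names: set[str]) -> list[Atom]:
    """Drop hydrogens bonded (≤1.3 Å) to any of the named heavy atoms."""
    heavy_coords = [residue.get_atom(n).coords for n in heavy_names if residue.get_atom(n)]
    kept = []
    for atom in residue.atoms:
        if atom.is_hydrogen and any(
            np.linalg.norm(atom.coords - hc) <= 1.3 for hc in heavy_coords
        ):
            continue
        kept.append(atom)
    return kept


def _h_atom(name: str, coords: np.ndarray) -> Atom:
    return Atom(name=name, element="H", coords=coords)


def add_ideal_hydrogens(residue: Residue, scenario: str) -> Residue:
    """Return a copy of ``residue`` with idealized hydrogens for ``scenario``.

    Scenarios: ``HID`` (ND1-protonated His), ``HIE`` (NE2-protonated),
    ``HIP`` (both), ``aromatic_CH_only`` (ring C–H, plus Trp NE1–H and Tyr
    O–H), ``lys_NZ3`` (ammonium), ``arg_guanidinium``.  Existing hydrogens on
    rebuilt sites are replaced; others are kept.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")

    if scenario == "lys_NZ3":
        return _lys_nz3(residue)
    if scenario == "arg_guanidinium":
        return _arg_guanidinium(residue)

    name = residue.name
    if name not in RING_BONDS:
        raise ValueError(f"scenario {scenario} needs an aromatic residue, got {name}")
    if scenario in ("HID", "HIE", "HIP") and name != "HIS":
        raise ValueError(f"scenario {scenario} applies to His only")

    ring = build_ring(residue, planarity_tol=math.inf)
    targets: list[tuple[str, str, float]] = []  # (heavy, H name, length)
    if name == "HIS":
        targets += [("CD2", "HD2", CH_LENGTH), ("CE1", "HE1", CH_LENGTH)]
        if scenario in ("HID", "HIP"):
            targets.append(("ND1", "HD1", NH_LENGTH))
        if scenario in ("HIE", "HIP"):
            targets.append(("NE2", "HE2", NH_LENGTH))
    elif name in ("PHE", "TYR"):
        targets += [
            ("CD1", "HD1", CH_LENGTH), ("CD2", "HD2", CH_LENGTH),
            ("CE1", "HE1", CH_LENGTH), ("CE2", "HE2", CH_LENGTH),
        ]
        if name == "PHE":
            targets.append(("CZ", "HZ", CH_LENGTH))
    elif name == "TRP":
        targets += [
            ("CD1", "HD1", CH_LENGTH), ("NE1", "HE1", NH_LENGTH),
            ("CE3", "HE3", CH_LENGTH), ("CZ3", "HZ3", CH_LENGTH),
            ("CH2", "HH2", CH_LENGTH), ("CZ2", "HZ2", CH_LENGTH),
        ]

    missing = [h for h, _, _ in targets if residue.get_atom(h) is None]
    if missing:
        raise ValueError(f"{residue.rid}: missing anchor atoms {missing}")

    strip = {h for h, _, _ in targets}
    if name == "HIS" and scenario in ("HID", "HIE", "HIP"):
        strip |= {"ND1", "NE2"}  # the scenario states the full ring protonation
    new_atoms = _strip_hydrogens_on(residue, strip)
    for heavy, hname, length in targets:
        pos = _bisector_h(residue, heavy, _ring_neighbors(name, heavy), length, ring.normal)
        new_atoms.append(_h_atom(hname, pos))

    if name == "TYR":
        oh, cz = residue.get_atom("OH"), residue.get_atom("CZ")
        if oh is not None and cz is not None:
            new_atoms = [
                a for a in new_atoms
                if not (a.is_hydrogen and np.linalg.norm(a.coords - oh.coords) <= 1.3)
            ]
            # hydroxyl H in the ring plane, C-O-H ~109.5° (rotamer fixed for determinism)
            new_atoms.append(
                _h_atom("HH", _rotated_in_plane(oh.coords, cz.coords, ring.normal, 109.5, OH_LENGTH))
            )
    return dataclasses.replace(residue, atoms=new_atoms)


def _rotated_in_plane(
    origin: np.ndarray, anchor: np.ndarray, normal: np.ndarray, angle_deg: float, length: float
) -> np.ndarray:
    v = _unit(anchor - origin)
    v = _unit(v - np.dot(v, normal) * normal)
    w = np.cross(normal, v)
    a = math.radians(angle_deg)
    return origin + length * (math.cos(a) * v + math.sin(a) * w)


def _lys_nz3(residue: Residue) -> Residue:
    nz, ce, cd = (residue.get_atom(n) for n in ("NZ", "CE", "CD"))
    if nz is None or ce is None or cd is None:
        raise ValueError(f"{residue.rid}: Lys needs NZ, CE, CD")
    atoms = _strip_hydrogens_on(residue, {"NZ"})
    for i, dihedral in enumerate((60.0, 180.0, 300.0), start=1):
        atoms.append(
            _h_atom(f"HZ{i}", _dihedral_h(nz.coords, ce.coords, cd.coords, NH_LENGTH, 109.47, dihedral))
        )
    return dataclasses.replace(residue, atoms=atoms)


def _arg_guanidinium(residue: Residue) -> Residue:
    needed = ("CD", "NE", "CZ", "NH1", "NH2")
    if any(residue.get_atom(n) is None for n in needed):
        raise ValueError(f"{residue.rid}: Arg needs {needed}")
    X = np.asarray([residue.get_atom(n).coords for n in ("NE", "CZ", "NH1", "NH2")])
    c = X.mean(axis=0)
    _, _, vt = np.linalg.svd(X - c)
    normal = _unit(vt[2])
    atoms = _strip_hydrogens_on(residue, {"NE", "NH1", "NH2"})
    ne, cz = residue.get_atom("NE"), residue.get_atom("CZ")
    # NE-H: in-plane external bisector of CD and CZ
    direction = -(_unit(residue.get_atom("CD").coords - ne.coords) + _unit(cz.coords - ne.coords))
    direction = direction - np.dot(direction, normal) * normal
    atoms.append(_h_atom("HE", ne.coords + NH_LENGTH * _unit(direction)))
    for nh, h1, h2 in (("NH1", "HH11", "HH12"), ("NH2", "HH21", "HH22")):
        n = residue.get_atom(nh)
        atoms.append(_h_atom(h1, _rotated_in_plane(n.coords, cz.coords, normal, 120.0, NH_LENGTH)))
        atoms.append(_h_atom(h2, _rotated_in_plane(n.coords, cz.coords, normal, -120.0, NH_LENGTH)))
    return dataclasses.replace(residue, atoms=atoms)
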