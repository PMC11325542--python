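"""Geometric classification of pairwise interactions.

Labels pairs as stacked (π–π), CH–π, cation–π and/or hydrogen-bonded using
configurable distance/angle thresholds, then optionally filters by a supplied
binding-energy table (entries are opaque kcal/mol values computed upstream).

Labels are a *set*: mixed geometries may legitimately satisfy several
criteria at once (e.g. a tilted stack whose ring C–H also points into the
partner ring face).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pair_mining import ResiduePair
from .ring_geometry import (
    AromaticRing,
    CationPiGeometry,
    CationSite,
    RingBuildError,
    aromatic_pair_geometry,
    AromaticPairGeometry,
    build_ring,
    cation_site,
    add_ideal_hydrogens,
    fold90,
)
from .structure_io import Atom, Residue, Structure

__all__ = [
    "GeometryThresholds",
    "InteractionLabelSet",
    "CHPiContact",
    "HBondResult",
    "classify_stacked",
    "classify_cation_pi",
    "classify_ch_pi",
    "classify_h_bond",
    "label_pair",
    "filter_by_energy",
    "summarize_energies",
    "pair_key",
    "read_energy_table",
]

log = logging.getLogger(__name__)

_H_BOND_COVALENT = 1.2  # Å, H considered bonded to its heavy atom


@dataclass(frozen=True)
class GeometryThresholds:
    """Classification cutoffs (standard literature criteria; all configurable
    and recorded in output headers)."""

    stack_max_D: float = 5.5
    stack_max_P: float = 30.0
    stack_min_T_theta2: float | None = None  # optional knob, off by default
    catpi_max_D: float = 6.0
    catpi_max_theta1: float = 60.0
    chpi_max_C_centroid: float = 4.5
    chpi_max_H_projection: float = 1.8
    chpi_min_CH_centroid_angle: float = 120.0
    hb_max_DA: float = 3.5
    hb_min_DHA_angle: float = 120.0
    hb_max_plane_elevation: float = 45.0
    energy_cutoff: float = -1.0

    def __post_init__(self):
        for d in (
            self.stack_max_D, self.catpi_max_D, self.chpi_max_C_centroid,
            self.chpi_max_H_projection, self.hb_max_DA,
        ):
            if not d > 0:
                raise ValueError("distance thresholds must be positive")
        for a in (
            self.stack_max_P, self.catpi_max_theta1, self.chpi_min_CH_centroid_angle,
            self.hb_min_DHA_angle, self.hb_max_plane_elevation,
        ):
            if not 0.0 <= a <= 180.0:
                raise ValueError("angle thresholds must lie in [0, 180]")


@dataclass(frozen=True)
class CHPiContact:
    donor_residue: str
    donor_carbon: str
    hydrogen: str
    c_centroid_distance: float
    h_projection: float
    ch_centroid_angle: float


@dataclass(frozen=True)
class HBondResult:
    is_bond: bool
    donor: str
    acceptor: str
    da_distance: float
    dha_angle: float
    plane_elevation: float | None = None


@dataclass
class InteractionLabelSet:
    labels: frozenset
    measurements: dict = field(default_factory=dict)
    scenario: str | None = None
    ch_pi_contacts: tuple = ()
    h_bonds: tuple = ()

    def __post_init__(self):
        if not self.labels:
            self.labels = frozenset({"other"})


def classify_stacked(geom: AromaticPairGeometry, thr: GeometryThresholds) -> bool:
    """True iff centroid distance and inter-plane angle are within the
    stacking cutoffs (rings approximately parallel)."""
    ok = geom.D <= thr.stack_max_D and geom.P <= thr.stack_max_P
    if ok and thr.stack_min_T_theta2 is not None:
        ok = geom.T_theta2 >= thr.stack_min_T_theta2
    return ok


def classify_cation_pi(geom: CationPiGeometry, thr: GeometryThresholds) -> bool:
    return geom.D <= thr.catpi_max_D and geom.theta1 <= thr.catpi_max_theta1


def _angle_at(b: np.ndarray, a: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c at vertex b, degrees."""
    u, v = a - b, c - b
    cu = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(1.0, max(-1.0, cu))))


def classify_ch_pi(
    donor_residue: Residue, acceptor_ring: AromaticRing, thr: GeometryThresholds
) -> list[CHPiContact]:
    """All C–H···π contacts from ``donor_residue`` into ``acceptor_ring``.

    A contact requires the donating carbon within ``chpi_max_C_centroid`` of
    the ring centroid, the hydrogen's projection onto the acceptor plane
    within ``chpi_max_H_projection`` of the centroid, and a C–H···centroid
    angle of at least ``chpi_min_CH_centroid_angle``.

    The donor must carry explicit hydrogens (experimental or idealized).
    """
    hydrogens = donor_residue.hydrogens()
    if not hydrogens:
        raise ValueError(f"{donor_residue.rid}: CH–π donor has no hydrogens")
    contacts: list[CHPiContact] = []
    centroid, normal = acceptor_ring.centroid, acceptor_ring.normal
    for carbon in donor_residue.atoms:
        if carbon.element.upper() != "C":
            continue
        d_cc = float(np.linalg.norm(carbon.coords - centroid))
        if d_cc > thr.chpi_max_C_centroid:
            continue
        for h in hydrogens:
            if np.linalg.norm(h.coords - carbon.coords) > _H_BOND_COVALENT:
                continue
            offset = h.coords - centroid
            in_plane = offset - np.dot(offset, normal) * normal
            proj = float(np.linalg.norm(in_plane))
            if proj > thr.chpi_max_H_projection:
                continue
            angle = _angle_at(h.coords, carbon.coords, centroid)
            if angle < thr.chpi_min_CH_centroid_angle:
                continue
            contacts.append(
                CHPiContact(
                    donor_residue=donor_residue.rid,
                    donor_carbon=carbon.name,
                    hydrogen=h.name,
                    c_centroid_distance=d_cc,
                    h_projection=proj,
                    ch_centroid_angle=angle,
                )
            )
    return contacts


def classify_h_bond(
    donor_atom: Atom,
    donor_h: Atom,
    acceptor_atom: Atom,
    his_ring: AromaticRing | None,
    thr: GeometryThresholds,
) -> HBondResult:
    """Donor–H···acceptor test.

    Checks donor–acceptor distance and the D–H–A angle; when either partner
    is a His ring nitrogen, additionally requires the bond vector to stay
    within ``hb_max_plane_elevation`` of the His ring plane (the in-plane
    lone-pair / N–H direction constraint).
    """
    da = float(np.linalg.norm(donor_atom.coords - acceptor_atom.coords))
    dha = _angle_at(donor_h.coords, donor_atom.coords, acceptor_atom.coords)
    elevation = None
    ok = da <= thr.hb_max_DA and dha >= thr.hb_min_DHA_angle
    if his_ring is not None:
        v = acceptor_atom.coords - donor_atom.coords
        s = abs(float(np.dot(v, his_ring.normal))) / float(np.linalg.norm(v))
        elevation = math.degrees(math.asin(min(1.0, s)))
        ok = ok and elevation <= thr.hb_max_plane_elevation
    return HBondResult(
        is_bond=ok,
        donor=donor_atom.name,
        acceptor=acceptor_atom.name,
        da_distance=da,
        dha_angle=dha,
        plane_elevation=elevation,
    )


# -- hydrogen scenarios per residue type -----------------------------------

def _scenario_for(residue: Residue, protonation_scenario: str) -> str | None:
    if residue.name == "HIS":
        return protonation_scenario
    if residue.name in ("PHE", "TYR", "TRP"):
        return "aromatic_CH_only"
    if residue.name == "LYS":
        return "lys_NZ3"
    if residue.name == "ARG":
        return "arg_guanidinium"
    return None


def _with_hydrogens(residue: Residue, protonation_scenario: str) -> Residue:
    """Residue with usable hydrogens: experimental ones are kept, otherwise
    idealized hydrogens are placed for the residue's scenario."""
    if residue.hydrogens():
        return residue
    scen = _scenario_for(residue, protonation_scenario)
    if scen is None:
        return residue
    try:
        return add_ideal_hydrogens(residue, scen)
    except (ValueError, RingBuildError) as exc:
        log.warning("hydrogen placement failed: %s", exc)
        return residue


def _attached_h(residue: Residue, heavy: Atom) -> list[Atom]:
    return [
        h for h in residue.hydrogens()
        if np.linalg.norm(h.coords - heavy.coords) <= _H_BOND_COVALENT
    ]


def _polar_atoms(residue: Residue) -> list[Atom]:
    return [a for a in residue.atoms if a.element.upper() in ("N", "O")]


def _his_ring_for(residue: Residue, atom: Atom) -> AromaticRing | None:
    if residue.name == "HIS" and atom.name in ("ND1", "NE2"):
        try:
            return build_ring(residue)
        except RingBuildError:
            return None
    return None


def _pair_h_bonds(
    res_a: Residue, res_b: Residue, thr: GeometryThresholds
) -> list[HBondResult]:
    """All donor→acceptor H-bonds between two hydrogenated residues.

    N/O atoms with attached hydrogens donate; O atoms and bare N atoms
    accept (a protonated nitrogen cannot accept).
    """
    bonds: list[HBondResult] = []
    for donor_res, acceptor_res in ((res_a, res_b), (res_b, res_a)):
        for donor in _polar_atoms(donor_res):
            hs = _attached_h(donor_res, donor)
            if not hs:
                continue
            for acceptor in _polar_atoms(acceptor_res):
                if acceptor.element.upper() == "N" and _attached_h(acceptor_res, acceptor):
                    continue
                ring = _his_ring_for(donor_res, donor) or _his_ring_for(acceptor_res, acceptor)
                for h in hs:
                    result = classify_h_bond(donor, h, acceptor, ring, thr)
                    if result.is_bond:
                        bonds.append(result)
    return bonds


def label_pair(
    pair: ResiduePair,
    structure: Structure,
    protonation_scenario: str,
    thr: GeometryThresholds | None = None,
) -> InteractionLabelSet:
    """Run every classifier applicable to the pair's family.

    Ring–ring pairs are tested for stacking, CH–π (both directions) and
    H-bonds; cation–π pairs for the cation–π criterion plus CH–π/H-bonds
    where donors exist.  Returns the label union, or ``{"other"}``.
    """
    thr = thr or GeometryThresholds()
    res_ref = structure.find_residue(pair.ref_id)
    res_par = structure.find_residue(pair.partner_id)
    if res_ref is None or res_par is None:
        raise ValueError(f"pair residues {pair.ref_id}/{pair.partner_id} not in structure")
    h_ref = _with_hydrogens(res_ref, protonation_scenario)
    h_par = _with_hydrogens(res_par, protonation_scenario)

    labels: set[str] = set()
    measurements: dict = {}
    contacts: list[CHPiContact] = []

    rings: dict[str, AromaticRing] = {}
    for res in (h_ref, h_par):
        try:
            rings[res.rid] = build_ring(res)
        except RingBuildError:
            pass

    if pair.family == "aromatic" and h_ref.rid in rings and h_par.rid in rings:
        geom = aromatic_pair_geometry(rings[h_ref.rid], rings[h_par.rid])
        measurements["aromatic_geometry"] = geom
        if classify_stacked(geom, thr):
            labels.add("stacked")

    if pair.family == "cation_pi":
        pi_res = h_ref if h_ref.rid == pair.pi_id else h_par
        cat_res = h_par if pi_res is h_ref else h_ref
        if pi_res.rid in rings:
            try:
                site = cation_site(cat_res, partner_centroid=rings[pi_res.rid].centroid)
                geom = cation_pi_geometry_safe(rings[pi_res.rid], site)
                if geom is not None:
                    measurements["cation_pi_geometry"] = geom
                    if classify_cation_pi(geom, thr):
                        labels.add("cation_pi")
            except (RingBuildError, ValueError) as exc:
                log.warning("cation–π geometry failed: %s", exc)

    for donor, acceptor in ((h_ref, h_par), (h_par, h_ref)):
        ring = rings.get(acceptor.rid)
        if ring is None or not donor.hydrogens():
            continue
        contacts.extend(classify_ch_pi(donor, ring, thr))
    if contacts:
        labels.add("ch_pi")

    h_bonds = tuple(_pair_h_bonds(h_ref, h_par, thr))
    if h_bonds:
        labels.add("h_bond")

    return InteractionLabelSet(
        labels=frozenset(labels),
        measurements=measurements,
        scenario=protonation_scenario,
        ch_pi_contacts=tuple(contacts),
        h_bonds=h_bonds,
    )


def cation_pi_geometry_safe(ring: AromaticRing, site: CationSite) -> CationPiGeometry | None:
    from .ring_geometry import cation_pi_geometry

    try:
        return cation_pi_geometry(ring, site)
    except ValueError:
        return None


def pair_key(pair: ResiduePair) -> str:
    return f"{pair.structure_id}:{pair.ref_id}:{pair.partner_id}"


def read_energy_table(path) -> dict[str, float]:
    """Whitespace-separated ``pair_id energy`` table (kcal/mol)."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'pair_id energy'")
            try:
                table[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad energy {parts[1]!r}") from exc
    return table


def filter_by_energy(
    labeled_pairs, energy_table: dict[str, float], cutoff: float = -1.0, key=pair_key
):
    """Keep pairs whose binding energy falls below ``cutoff``.

    Pairs without an energy entry are dropped (count logged).
    """
    kept, missing = [], 0
    for item in labeled_pairs:
        pid = key(item)
        if pid not in energy_table:
            missing += 1
            continue
        if energy_table[pid] < cutoff:
            kept.append(item)
    if missing:
        log.info("filter_by_energy: %d pairs had no energy entry and were dropped", missing)
    return kept


def summarize_energies(records) -> pd.DataFrame:
    """Mean ± sample SD of binding energies per (family, label, phase).

    ``records``: iterable of (family, label, phase, energy).  Singleton cells
    report SD 0 and are flagged by n=1; empty cells are simply absent.
    """
    df = pd.DataFrame(records, columns=["family", "label", "phase", "energy"])
    if df.empty:
        return pd.DataFrame(columns=["family", "label", "phase", "mean", "sd", "n"])
    out = (
        df.groupby(["family", "label", "phase"], sort=True)["energy"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out
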