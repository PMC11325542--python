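"""His protonation/tautomer state assignment.

Two independent routes:

* neutron structures — read the deuterium positions directly: a D on NE2
  only is the ε-tautomer, on ND1 only the δ-tautomer, on both the
  positively charged form;
* X-ray structures — hypothesize each of the three protonation scenarios
  (ND1-H, NE2-H, both), place idealized hydrogens, census the H-bonds the
  ring nitrogens could make with *any* neighboring atom (side chains,
  backbone, waters) and keep only His whose scenarios agree on a single
  status.  A ring nitrogen accepting an H-bond must be deprotonated; both
  nitrogens donating means the ring is protonated.

Metal-coordinated His are called neutral up front and skipped by the
H-bond census.  A pKa table (computed upstream) can stratify His into
low / medium / high acidity groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .interaction_classify import GeometryThresholds, classify_h_bond
from .ring_geometry import RingBuildError, add_ideal_hydrogens, build_ring
from .structure_io import DEFAULT_METALS, Atom, Residue, Structure, find_metals

__all__ = [
    "TautomerCall",
    "ProtonationCall",
    "HBondEvidence",
    "PKA_LOW_BOUND",
    "PKA_HIGH_BOUND",
    "tautomer_from_deuterium",
    "infer_protonation_hbond",
    "metal_bound_neutral",
    "categorize_pka",
    "pka_group_fractions",
    "read_pka_table",
]

PKA_LOW_BOUND = 5.3
PKA_HIGH_BOUND = 7.3

_ND_BOND_CUTOFF = 1.3  # Å — ring N–D bond inferred by distance (no CONECT)
_SCENARIO_PROTONATED = {"HID": ("ND1",), "HIE": ("NE2",), "HIP": ("ND1", "NE2")}
# tautomer implied when the named nitrogen is found to accept (is deprotonated)
_ACCEPT_IMPLIES = {"ND1": "epsilon0", "NE2": "delta0"}


@dataclass(frozen=True)
class TautomerCall:
    state: str  # epsilon0 | delta0 | positive | not_determinable
    evidence: tuple[str, ...] = ()  # ring nitrogens carrying deuterium


@dataclass(frozen=True)
class HBondEvidence:
    scenario: str
    ring_nitrogen: str
    role: str  # "donor" | "acceptor"
    partner_residue: str
    partner_atom: str
    confidence: str = "normal"  # "low" for orientation-free water fallback


@dataclass(frozen=True)
class ProtonationCall:
    state: str  # neutral | neutral_metal | positive | undetermined
    tautomer: str | None = None  # epsilon0 | delta0, set when state == neutral
    evidence: tuple[HBondEvidence, ...] = ()


def tautomer_from_deuterium(his_residue: Residue) -> TautomerCall:
    """Tautomer from deuterium bonded (≤1.3 Å) to the ring nitrogens."""
    if his_residue.name != "HIS":
        raise ValueError(f"{his_residue.rid} is not a His residue")
    carriers = []
    for n_name in ("ND1", "NE2"):
        n = his_residue.get_atom(n_name)
        if n is None:
            continue
        for atom in his_residue.atoms:
            if atom.is_deuterium and np.linalg.norm(atom.coords - n.coords) <= _ND_BOND_CUTOFF:
                carriers.append(n_name)
                break
    if not carriers:
        return TautomerCall("not_determinable")
    if len(carriers) == 2:
        return TautomerCall("positive", tuple(carriers))
    state = "epsilon0" if carriers[0] == "NE2" else "delta0"
    return TautomerCall(state, tuple(carriers))


def metal_bound_neutral(
    structure: Structure,
    his_residue: Residue,
    coordination_cutoff: float = 3.0,
    metal_names=DEFAULT_METALS,
) -> bool:
    """True iff a ring nitrogen coordinates a metal (within the cutoff)."""
    sites = find_metals(structure, metal_names)
    if not sites:
        return False
    for n_name in ("ND1", "NE2"):
        n = his_residue.get_atom(n_name)
        if n is None:
            continue
        for _, coords, _ in sites:
            if np.linalg.norm(n.coords - coords) <= coordination_cutoff:
                return True
    return False


def _neighbor_atoms(
    structure: Structure, his_residue: Residue, radius: float
) -> list[tuple[Residue, Atom]]:
    """Heavy N/O atoms of other residues (incl. waters) within ``radius`` of
    either His ring nitrogen."""
    ns = [his_residue.get_atom(n) for n in ("ND1", "NE2")]
    ns = [a.coords for a in ns if a is not None]
    if not ns:
        return []
    out = []
    for res in list(structure.residues) + list(structure.hetero):
        if res.rid == his_residue.rid and res.name == his_residue.name:
            continue
        for atom in res.atoms:
            if atom.is_hydrogen or atom.element.upper() not in ("N", "O"):
                continue
            if any(np.linalg.norm(atom.coords - nc) <= radius for nc in ns):
                out.append((res, atom))
    return out


def _attached_h(residue: Residue, heavy: Atom) -> list[Atom]:
    return [
        h for h in residue.hydrogens()
        if np.linalg.norm(h.coords - heavy.coords) <= 1.2
    ]


def _donates_into(partner_res: Residue, partner_atom: Atom, target: Atom) -> bool:
    """Does the partner atom's own hydrogen point at ``target``?  Such an
    atom is the donor of that contact, not an acceptor for it."""
    for h in _attached_h(partner_res, partner_atom):
        if np.linalg.norm(h.coords - target.coords) <= 2.6:
            u = partner_atom.coords - h.coords
            v = target.coords - h.coords
            c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            if math.degrees(math.acos(min(1.0, max(-1.0, c)))) >= 90.0:
                return True
    return False


def infer_protonation_hbond(
    structure: Structure,
    his_residue: Residue,
    thresholds: GeometryThresholds | None = None,
    neighbor_radius: float = 4.0,
    coordination_cutoff: float = 3.0,
    metal_names=DEFAULT_METALS,
) -> ProtonationCall:
    """Three-scenario H-bond-pattern protonation inference for one His.

    Metal-coordinated His short-circuit to ``neutral_metal``.  Otherwise each
    protonation scenario is hydrogenated and censused; a state is returned
    only when every scenario that yields evidence points at the same status,
    and at least one scenario is supported by more than one H-bond.
    """
    thr = thresholds or GeometryThresholds()
    if metal_bound_neutral(structure, his_residue, coordination_cutoff, metal_names):
        return ProtonationCall(state="neutral_metal")

    neighbors = _neighbor_atoms(structure, his_residue, neighbor_radius)
    try:
        his_ring = build_ring(his_residue)
    except RingBuildError:
        return ProtonationCall(state="undetermined")

    evidence: list[HBondEvidence] = []
    conclusions: set[tuple[str, str | None]] = set()  # (state, tautomer)
    max_scenario_bonds = 0

    for scenario, protonated in _SCENARIO_PROTONATED.items():
        try:
            his_h = add_ideal_hydrogens(his_residue, scenario)
        except (ValueError, RingBuildError):
            continue
        scen_evidence: list[HBondEvidence] = []
        donors_found: set[str] = set()
        acceptors_found: set[str] = set()

        for n_name in ("ND1", "NE2"):
            ring_n = his_h.get_atom(n_name)
            if ring_n is None:
                continue
            if n_name in protonated:
                hs = _attached_h(his_h, ring_n)
                for res, atom in neighbors:
                    # a partner that is itself donating into this nitrogen is
                    # not available as an acceptor for the nitrogen's proton
                    if _donates_into(res, atom, ring_n):
                        continue
                    if atom.element.upper() == "N" and _attached_h(res, atom):
                        continue  # protonated nitrogens do not accept
                    for h in hs:
                        result = classify_h_bond(ring_n, h, atom, his_ring, thr)
                        if result.is_bond:
                            donors_found.add(n_name)
                            scen_evidence.append(
                                HBondEvidence(scenario, n_name, "donor", res.rid, atom.name)
                            )
            else:
                for res, atom in neighbors:
                    hs = _attached_h(res, atom)
                    if hs:
                        for h in hs:
                            result = classify_h_bond(atom, h, ring_n, his_ring, thr)
                            if result.is_bond:
                                acceptors_found.add(n_name)
                                scen_evidence.append(
                                    HBondEvidence(scenario, n_name, "acceptor", res.rid, atom.name)
                                )
                    elif res.is_water:
                        # hydrogen-free water: orientation-free fallback,
                        # distance criterion only, logged as low confidence
                        da = float(np.linalg.norm(atom.coords - ring_n.coords))
                        v = ring_n.coords - atom.coords
                        s = abs(float(np.dot(v, his_ring.normal))) / float(np.linalg.norm(v))
                        elev = math.degrees(math.asin(min(1.0, s)))
                        if da <= thr.hb_max_DA and elev <= thr.hb_max_plane_elevation:
                            acceptors_found.add(n_name)
                            scen_evidence.append(
                                HBondEvidence(
                                    scenario, n_name, "acceptor", res.rid, atom.name,
                                    confidence="low",
                                )
                            )

        max_scenario_bonds = max(max_scenario_bonds, len(scen_evidence))
        evidence.extend(scen_evidence)
        if acceptors_found:
            # an accepting nitrogen is deprotonated — neutral, fixed tautomer
            for n_name in sorted(acceptors_found):
                conclusions.add(("neutral", _ACCEPT_IMPLIES[n_name]))
        elif donors_found == {"ND1", "NE2"}:
            conclusions.add(("positive", None))

    if max_scenario_bonds <= 1:
        return ProtonationCall(state="undetermined", evidence=tuple(evidence))
    if len(conclusions) != 1:
        return ProtonationCall(state="undetermined", evidence=tuple(evidence))
    state, tautomer = next(iter(conclusions))
    return ProtonationCall(state=state, tautomer=tautomer, evidence=tuple(evidence))


def categorize_pka(pka_value: float) -> str:
    """low (< 5.3), high (> 7.3) or medium (5.3 ≤ pKa ≤ 7.3, bounds inclusive)."""
    if not math.isfinite(pka_value):
        raise ValueError(f"non-finite pKa value {pka_value}")
    if pka_value < PKA_LOW_BOUND:
        return "low"
    if pka_value > PKA_HIGH_BOUND:
        return "high"
    return "medium"


def pka_group_fractions(calls: dict[str, str], labeled_pairs) -> dict:
    """Fractions of each pKa category per (pair family, interaction label).

    ``calls`` maps His residue id → category; ``labeled_pairs`` yields
    ``(family, interaction_label, his_residue_id)`` records.  For each
    non-empty (family, label) cell the counts over the three categories are
    normalized to sum to 1; empty cells are omitted.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for family, label, his_rid in labeled_pairs:
        if his_rid not in calls:
            raise KeyError(f"no pKa category for His {his_rid}")
        cell = counts.setdefault((family, label), {"low": 0, "medium": 0, "high": 0})
        cell[calls[his_rid]] += 1
    fractions: dict[tuple[str, str], dict[str, float]] = {}
    for cell_key, cell in counts.items():
        total = sum(cell.values())
        if total == 0:
            continue
        fractions[cell_key] = {cat: n / total for cat, n in cell.items()}
    return fractions


def read_pka_table(path) -> dict[str, float]:
    """Whitespace-separated ``structure_id chain resnum pka`` table.

    Returns a mapping ``"structure_id/chain:resnum" -> value``.
    """
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'structure chain resnum pka'")
            sid, chain, resnum, pka = parts
            table[f"{sid}/{chain}:{resnum}"] = float(pka)
    return table
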