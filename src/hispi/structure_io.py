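"""Reading, writing and filtering of protein structures.

Exposes a deliberately small atom/residue/structure model on top of
Biopython's PDB/mmCIF parsers.  The model keeps alternate locations,
occupancies and hydrogen/deuterium atoms so that downstream protonation
analysis can use them; descriptor math only ever touches heavy atoms.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureFilter",
    "MetalSite",
    "DEFAULT_METALS",
    "read_structure",
    "resolve_altlocs",
    "passes_filters",
    "find_metals",
    "write_pdb",
]

#: Metal elements recognised by default (configurable everywhere they are used).
DEFAULT_METALS = ("ZN", "CA", "MG", "MN", "FE", "CO", "NI", "CU", "NA", "K")

_WATER_NAMES = {"HOH", "DOD", "WAT", "D2O"}


@dataclass
class Atom:
    """A single atom site."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_deuterium: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.is_deuterium and self.element.upper() not in ("D", "H"):
            raise ValueError(f"atom {self.name}: is_deuterium set but element is {self.element}")

    @property
    def is_hydrogen(self) -> bool:
        """True for protium and deuterium alike."""
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    is_hetero: bool = False

    @property
    def rid(self) -> str:
        """Stable residue identifier, e.g. ``A:42`` or ``A:42B``."""
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}"

    @property
    def is_water(self) -> bool:
        return self.name in _WATER_NAMES

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def hydrogens(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_hydrogen]


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)
    hetero: list[Residue] = field(default_factory=list)
    resolution: float | None = None
    r_factor: float | None = None
    method: str = "other"  # {"xray", "neutron", "other"}

    def sorted(self) -> "Structure":
        """Return a copy with residues in canonical (chain, seq, icode) order."""
        key = lambda r: (r.chain_id, r.seq_number, r.insertion_code)
        return dataclasses.replace(
            self, residues=sorted(self.residues, key=key), hetero=sorted(self.hetero, key=key)
        )

    def find_residue(self, rid: str) -> Residue | None:
        for res in list(self.residues) + list(self.hetero):
            if res.rid == rid:
                return res
        return None


@dataclass
class StructureFilter:
    """Acceptance filter mirroring a curated high-resolution workflow.

    ``None`` for a bound disables that check; missing structure metadata
    fails an *enabled* check (conservative default).
    """

    max_resolution: float | None = 1.8
    max_r_factor: float | None = 0.18
    min_length: int = 40
    max_length: int = 10_000
    allowed_methods: tuple[str, ...] = ("xray",)

    def __post_init__(self) -> None:
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be < max_length")


MetalSite = tuple  # (element, coords, residue) — see find_metals


def _method_label(raw: str | None) -> str:
    if not raw:
        return "other"
    raw = raw.lower()
    if "neutron" in raw:
        return "neutron"
    if "x-ray" in raw or "xray" in raw:
        return "xray"
    return "other"


def _scan_pdb_r_factor(path: Path) -> float | None:
    """Pull the working-set R value out of REMARK 3 (Biopython does not)."""
    for line in path.read_text(errors="replace").splitlines():
        if not line.startswith("REMARK   3"):
            continue
        u = line.upper()
        if "R VALUE" in u and ("WORKING SET" in u or "WORKING + TEST SET" in u):
            tail = line.split(":", 1)
            if len(tail) == 2:
                try:
                    return float(tail[1].strip())
                except ValueError:
                    continue
    return None


def _convert_biopdb(sid: str, model) -> tuple[list[Residue], list[Residue]]:
    polymer: list[Residue] = []
    hetero: list[Residue] = []
    for chain in model:
        for res in chain:
            hetfield, seq, icode = res.id
            atoms = []
            for a in res.get_unpacked_list():
                element = (a.element or "").strip() or a.get_name()[:1]
                atoms.append(
                    Atom(
                        name=a.get_name(),
                        element=element,
                        coords=np.array(a.coord, dtype=float),
                        occupancy=min(max(a.get_occupancy() or 1.0, 0.0), 1.0),
                        altloc=a.get_altloc().strip(),
                        is_deuterium=element.upper() == "D",
                    )
                )
            residue = Residue(
                chain_id=chain.id,
                seq_number=seq,
                name=res.resname.strip(),
                atoms=atoms,
                insertion_code=icode.strip(),
                is_hetero=(hetfield.strip() != ""),
            )
            (hetero if residue.is_hetero else polymer).append(residue)
    return polymer, hetero


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model of multi-model files is used.  Deuterium atoms are
    flagged; resolution, R-factor and experimental method are captured when
    present in the file.

    Parameters
    ----------
    path : file to read.
    format : ``"pdb"`` or ``"mmcif"``; inferred from the extension if omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")

    from Bio.PDB import MMCIFParser, PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if format == "pdb":
            parser = PDBParser(QUIET=True)
            bs = parser.get_structure(path.stem, str(path))
            resolution = bs.header.get("resolution")
            method = _method_label(bs.header.get("structure_method"))
            r_factor = _scan_pdb_r_factor(path)
        else:
            parser = MMCIFParser(QUIET=True)
            bs = parser.get_structure(path.stem, str(path))
            from Bio.PDB.MMCIF2Dict import MMCIF2Dict

            d = MMCIF2Dict(str(path))
            resolution = _first_float(
                d, "_refine.ls_d_res_high", "_reflns.d_resolution_high"
            )
            r_factor = _first_float(
                d, "_refine.ls_R_factor_R_work", "_refine.ls_R_factor_obs"
            )
            raw_method = d.get("_exptl.method")
            if isinstance(raw_method, list):
                raw_method = raw_method[0] if raw_method else None
            method = _method_label(raw_method)

    models = list(bs)
    if not models:
        raise ValueError(f"{path}: no coordinates")
    polymer, hetero = _convert_biopdb(path.stem, models[0])
    if not polymer and not hetero:
        raise ValueError(f"{path}: no coordinates")
    return Structure(
        id=path.stem,
        residues=polymer,
        hetero=hetero,
        resolution=resolution,
        r_factor=r_factor,
        method=method,
    ).sorted()


def _first_float(d: dict, *keys: str) -> float | None:
    for k in keys:
        v = d.get(k)
        if isinstance(v, list):
            v = v[0] if v else None
        if v in (None, "?", "."):
            continue
        try:
            return float(v)
        except (TypeError, ValueError):
            continue
    return None


def _resolve_residue_altlocs(residue: Residue) -> Residue:
    chosen: dict[str, Atom] = {}
    for atom in residue.atoms:
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
        elif atom.occupancy > prev.occupancy or (
            atom.occupancy == prev.occupancy and (atom.altloc or "") < (prev.altloc or "")
        ):
            # higher occupancy wins; ties break to the first altloc
            chosen[atom.name] = atom
    return dataclasses.replace(residue, atoms=list(chosen.values()))


def resolve_altlocs(structure: Structure, policy: str = "highest_occupancy") -> Structure:
    """Keep at most one atom per (residue, atom name).

    Highest occupancy wins; ties break to the lexicographically first altloc.
    Idempotent.
    """
    if policy != "highest_occupancy":
        raise ValueError(f"unknown altloc policy {policy!r}")
    return dataclasses.replace(
        structure,
        residues=[_resolve_residue_altlocs(r) for r in structure.residues],
        hetero=[_resolve_residue_altlocs(r) for r in structure.hetero],
    )


def passes_filters(structure: Structure, filt: StructureFilter) -> bool:
    """True iff the structure satisfies every enabled bound of ``filt``."""
    if filt.max_resolution is not None:
        if structure.resolution is None or structure.resolution > filt.max_resolution:
            return False
    if filt.max_r_factor is not None:
        if structure.r_factor is None or structure.r_factor > filt.max_r_factor:
            return False
    n = len(structure.residues)
    if not filt.min_length <= n <= filt.max_length:
        return False
    if filt.allowed_methods is not None and structure.method not in filt.allowed_methods:
        return False
    return True


def find_metals(
    structure: Structure, metal_names: Sequence[str] = DEFAULT_METALS
) -> list[tuple[str, np.ndarray, Residue]]:
    """All hetero atom sites whose element is in ``metal_names``.

    Returns (element, coords, parent residue) triples.
    """
    wanted = {m.upper() for m in metal_names}
    sites = []
    for res in structure.hetero:
        if res.is_water:
            continue
        for atom in res.atoms:
            if atom.element.upper() in wanted:
                sites.append((atom.element.upper(), atom.coords, res))
    return sites


# ---------------------------------------------------------------------------
# PDB writing (used by the synthetic generator and representative export)
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4 or len(element) >= 2:
        return name.ljust(4)[:4]
    return (" " + name).ljust(4)


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a structure as a plain-text PDB file.

    Metadata (method, resolution, R-factor) is emitted as EXPDTA/REMARK
    records so that read → write → read round-trips preserve it.
    """
    path = Path(path)
    lines: list[str] = []
    method_str = {"xray": "X-RAY DIFFRACTION", "neutron": "NEUTRON DIFFRACTION"}.get(
        structure.method
    )
    lines.append(f"HEADER    SYNTHETIC{'':43}{structure.id[:4].upper():>4}")
    if method_str:
        lines.append(f"EXPDTA    {method_str}")
    if structure.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {structure.resolution:5.2f} ANGSTROMS.")
    if structure.r_factor is not None:
        lines.append(
            f"REMARK   3   R VALUE            (WORKING SET) : {structure.r_factor:.3f}"
        )
    serial = 1
    for res, record in [(r, "ATOM") for r in structure.residues] + [
        (r, "HETATM") for r in structure.hetero
    ]:
        for atom in res.atoms:
            x, y, z = atom.coords
            lines.append(
                f"{record:<6}{serial:>5} {_format_atom_name(atom.name, atom.element)}"
                f"{atom.altloc or ' '}{res.name:>3} {res.chain_id}"
                f"{res.seq_number:>4}{res.insertion_code or ' '}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element.upper():>2}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
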