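"""Canonical heavy-atom representation of a protein complex.

A complex is parsed from a PDB file into a flat, ordered list of
:class:`Atom` records: all heavy protein atoms of the requested chains plus
the oxygen atoms of crystallographic waters.  Hydrogens are dropped, alternate
locations are collapsed to the highest-occupancy conformer, and non-water
heteroatoms are excluded unless explicitly requested.  Each atom carries a van
der Waals radius and a (possibly empty) set of chemistry classes used later
for contact typing:

* ``POSITIVE`` / ``NEGATIVE`` -- formally charged side-chain atoms
  (salt-bridge partners),
* ``DONOR`` / ``ACCEPTOR`` -- hydrogen-bond donors and acceptors.

Both lookup tables ship as editable JSON files under ``dbac/data`` so an
alternative radius set or atom-class dictionary can be swapped in without
touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
DONOR = "DONOR"
ACCEPTOR = "ACCEPTOR"

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})

#: Atoms that survive mutation to alanine (plus the chain terminus).
ALANINE_REMAINDER = frozenset({"N", "CA", "C", "O", "CB", "OXT"})

ResidueId = tuple[str, int, str]  # (chain id, residue number, insertion code)


def _load_packaged_json(name: str) -> dict:
    with resources.files("dbac.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class Atom:
    """One heavy atom (or water oxygen) of a complex."""

    serial: int
    name: str
    residue_name: str
    residue_id: ResidueId
    element: str
    coords: tuple[float, float, float]
    is_water: bool
    vdw_radius: float
    chem_classes: frozenset[str]

    @property
    def chain(self) -> str:
        return self.residue_id[0]

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"non-positive radius for atom {self.name}")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Structure:
    """Ordered heavy atoms of a complex plus the chain partition.

    ``side_a`` / ``side_b`` name the two interacting sides of the complex.
    Waters belong to neither side.  The partition may be left empty for
    single-body calculations (surface areas, burial levels); operations on
    the interface require both sides and raise otherwise.
    """

    atoms: list[Atom]
    side_a: frozenset[str] = field(default_factory=frozenset)
    side_b: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.side_a = frozenset(self.side_a)
        self.side_b = frozenset(self.side_b)
        if self.side_a & self.side_b:
            raise ValueError("chain partition sides overlap: "
                             f"{sorted(self.side_a & self.side_b)}")
        if self.side_a or self.side_b:
            known = self.side_a | self.side_b
            stray = {a.chain for a in self.atoms
                     if not a.is_water and a.chain not in known}
            if stray:
                raise ValueError(f"chains outside the partition: {sorted(stray)}")
        seen: set[tuple[ResidueId, str]] = set()
        for a in self.atoms:
            key = (a.residue_id, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} after altloc resolution")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.asarray([a.coords for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.asarray([a.vdw_radius for a in self.atoms], dtype=float)

    def water_mask(self) -> np.ndarray:
        return np.asarray([a.is_water for a in self.atoms], dtype=bool)

    def side_of(self, atom: Atom) -> str | None:
        """'A', 'B' or None (waters / unpartitioned chains)."""
        if atom.is_water:
            return None
        if atom.chain in self.side_a:
            return "A"
        if atom.chain in self.side_b:
            return "B"
        return None

    def require_partition(self) -> None:
        if not self.side_a or not self.side_b:
            raise ValueError("both sides of the chain partition must be set "
                             "and non-empty for interface operations")

    def residue_atoms(self, residue_id: ResidueId) -> list[int]:
        """Atom indices of one residue, in file order."""
        idx = [i for i, a in enumerate(self.atoms) if a.residue_id == residue_id]
        if not idx:
            raise KeyError(f"residue {residue_id} not in structure")
        return idx

    def residue_ids(self) -> list[ResidueId]:
        """Unique non-water residue ids in first-appearance order."""
        out: list[ResidueId] = []
        seen: set[ResidueId] = set()
        for a in self.atoms:
            if not a.is_water and a.residue_id not in seen:
                seen.add(a.residue_id)
                out.append(a.residue_id)
        return out


class ChemistryTables:
    """Van der Waals radii and atom chemistry classes, loaded from JSON."""

    def __init__(self, radii_path: str | Path | None = None,
                 classes_path: str | Path | None = None) -> None:
        if radii_path is None:
            raw = _load_packaged_json("vdw_radii.json")
        else:
            raw = json.loads(Path(radii_path).read_text())
        self.radii: dict[str, float] = {k: float(v)
                                        for k, v in raw["radii"].items()}
        if classes_path is None:
            self._cls = _load_packaged_json("chem_classes.json")
        else:
            self._cls = json.loads(Path(classes_path).read_text())

    def vdw_radius(self, element: str, is_water: bool = False) -> float:
        """Radius in Angstrom for an element (water oxygen has its own entry)."""
        key = "OW" if is_water else element.upper()
        try:
            return self.radii[key]
        except KeyError:
            raise KeyError(f"no van der Waals radius for element {element!r}; "
                           "extend the radius table") from None

    def _in_table(self, table: str, residue_name: str, atom_name: str) -> bool:
        tab = self._cls.get(table, {})
        return (atom_name in tab.get(residue_name, ())
                or atom_name in tab.get("*", ()))

    def chem_classes(self, residue_name: str, atom_name: str,
                     is_water: bool = False) -> frozenset[str]:
        """Chemistry classes of an atom; unknown atoms get the empty set."""
        if is_water or residue_name in WATER_RESNAMES:
            return frozenset({DONOR, ACCEPTOR})
        out = set()
        if self._in_table("positive", residue_name, atom_name):
            out.add(POSITIVE)
        if self._in_table("negative", residue_name, atom_name):
            out.add(NEGATIVE)
        if (self._in_table("donor", residue_name, atom_name)
                and atom_name not in self._cls.get("donor_exceptions", {})
                .get(residue_name, ())):
            out.add(DONOR)
        # charged N-H / O-H groups donate as well
        if POSITIVE in out:
            out.add(DONOR)
        if self._in_table("acceptor", residue_name, atom_name):
            out.add(ACCEPTOR)
        if NEGATIVE in out:
            out.add(ACCEPTOR)
        return frozenset(out)


_DEFAULT_TABLES: ChemistryTables | None = None


def default_tables() -> ChemistryTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = ChemistryTables()
    return _DEFAULT_TABLES


def assign_vdw_radius(element: str, is_water: bool = False,
                      tables: ChemistryTables | None = None) -> float:
    return (tables or default_tables()).vdw_radius(element, is_water)


def assign_chem_classes(residue_name: str, atom_name: str,
                        is_water: bool = False,
                        tables: ChemistryTables | None = None) -> frozenset[str]:
    return (tables or default_tables()).chem_classes(residue_name, atom_name,
                                                     is_water)


def _pick_altloc(group: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties go to the alphabetically first altloc
    return sorted(group, key=lambda a: (-a.occ, a.altloc or "~"))[0]


def read_pdb(path: str | Path,
             side_a: Iterable[str] | None = None,
             side_b: Iterable[str] | None = None,
             keep_waters: bool = True,
             het_include: Iterable[str] = (),
             tables: ChemistryTables | None = None) -> Structure:
    """Parse a PDB file into a heavy-atom :class:`Structure`.

    Only the first model is read.  Hydrogens (and deuteriums) are discarded.
    Waters keep only their oxygen.  Non-water heteroatom residues are skipped
    unless their residue name appears in ``het_include``.  When a chain
    partition is given, protein atoms are restricted to the listed chains;
    waters are always taken from every chain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tables = tables or default_tables()
    side_a = frozenset(side_a or ())
    side_b = frozenset(side_b or ())
    wanted = side_a | side_b
    het_include = frozenset(het_include)

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            is_water = res.name in WATER_RESNAMES
            if is_water:
                if not keep_waters:
                    continue
            else:
                if wanted and chain.name not in wanted:
                    continue
                if res.het_flag == "H" and res.name not in het_include:
                    continue
            icode = res.seqid.icode.strip()
            rid: ResidueId = (chain.name, res.seqid.num, icode)
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                if at.element.is_hydrogen:
                    continue
                if is_water and at.element.name != "O":
                    continue
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                at = _pick_altloc(group)
                elem = at.element.name
                atoms.append(Atom(
                    serial=at.serial,
                    name=name,
                    residue_name=res.name,
                    residue_id=rid,
                    element=elem,
                    coords=(at.pos.x, at.pos.y, at.pos.z),
                    is_water=is_water,
                    vdw_radius=tables.vdw_radius(elem, is_water),
                    chem_classes=tables.chem_classes(res.name, name, is_water),
                ))

    for side, label in ((side_a, "side_a"), (side_b, "side_b")):
        present = {a.chain for a in atoms if not a.is_water}
        missing = side - present
        if missing:
            raise ValueError(f"{path}: no atoms found for {label} "
                             f"chain(s) {sorted(missing)}")
    if not atoms:
        raise ValueError(f"{path}: no atoms parsed")
    return Structure(atoms=atoms, side_a=side_a, side_b=side_b)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure back out as minimal PDB ATOM/HETATM records."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        record = "HETATM" if a.is_water else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        chain, resnum, icode = a.residue_id
        x, y, z = a.coords
        lines.append(
            f"{record}{i:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
            f"{chain[:1]:1s}{resnum:4d}{icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def drop_atoms(structure: Structure, drop: Sequence[int]) -> Structure:
    """New structure without the atoms at the given indices (order kept)."""
    dropset = set(drop)
    kept = [a for i, a in enumerate(structure.atoms) if i not in dropset]
    return Structure(atoms=kept, side_a=structure.side_a,
                     side_b=structure.side_b)
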