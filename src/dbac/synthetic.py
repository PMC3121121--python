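"""Deterministic synthetic fixtures: lattice blocks, planted toy complexes
and labelled feature datasets.

These generators make every stage of the pipeline testable without any
structure downloads.  Each returns its own ground truth, computed either by
construction or by the independent brute-force pipeline in
:mod:`dbac.bruteforce` (which shares no code with the production path).

* :func:`make_lattice_block` -- a cubic block of carbon-like atoms with
  reference burial levels for checking graph construction and the
  shortest-path solve.
* :func:`make_toy_complex` -- a two-chain mini complex whose planted
  residues form a requested number of Type-I/II/III cross-chain contacts,
  embedded in solid carbon balls sized to force a requested burial band.
* :func:`make_feature_dataset` -- labelled DBAC-style feature tables with
  controllable class separation for exercising the SVM protocol.

The toy-complex geometry is unphysical on purpose (pseudo-residues may have
atoms tens of Angstrom apart): what matters is that the atom names and
residue names are real, so contact typing runs through the same chemistry
dictionary as for real structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bruteforce as bf
from .features import AC_COLUMNS, DBAC_COLUMNS
from .structure import (ACCEPTOR, ALANINE_REMAINDER, DONOR, NEGATIVE,
                        POSITIVE, Atom, Structure, default_tables)

#: Solid-ball radius (A) that buries the central planted contact to each
#: burial band, for the 3.0 A carbon lattice used by the toy complexes.
BAND_RADII = {0: 0.0, 1: 6.5, 2: 10.0, 3: 15.0}

_LATTICE_SPACING = 3.0  # A, toy-complex filler lattice
_PAIR_DIST = 3.1        # A, planted site-partner distance
_CLASH = 2.2            # A, filler atoms closer than this to a planted atom are dropped

#: Planted-residue site atoms by contact type (histidine pseudo-residue).
_SITE_ATOMS = {"I": ["NE2"], "II": ["ND1"], "III": ["CG", "CD2", "CE1"]}
#: Partner (atom name, residue name) by contact type.
_PARTNER = {"I": ("OD1", "ASP"), "II": ("O", "GLY"), "III": ("CD1", "LEU")}

_DIRECTIONS = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                        [-1, 0, 0], [0, -1, 0], [0, 0, -1]], dtype=float)


def _mk_atom(serial, name, resname, rid, element, xyz, is_water=False,
             tables=None) -> Atom:
    tables = tables or default_tables()
    return Atom(serial=serial, name=name, residue_name=resname,
                residue_id=rid, element=element,
                coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                is_water=is_water,
                vdw_radius=tables.vdw_radius(element, is_water),
                chem_classes=tables.chem_classes(resname, name, is_water))


def make_lattice_block(nx: int, ny: int, nz: int, spacing: float = 3.8,
                       seed: int = 0) -> tuple[Structure, np.ndarray]:
    """Cubic block of carbon atoms plus reference burial levels.

    Spacing must lie in (2.0, 6.5) A so lattice neighbours are contacts
    under the carbon-carbon distance gate.  A deterministic sub-milli-A
    jitter breaks the exact cosphericity of the cubic lattice.  The returned
    levels come from the independent brute-force pipeline (Biopython SASA,
    simplex-enumerated Delaunay, networkx BFS).
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("lattice dims must be >= 1")
    if not 2.0 < spacing < 6.5:
        raise ValueError("spacing must be in (2.0, 6.5) A to form contacts")
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 0
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                serial += 1
                xyz = (np.array([ix, iy, iz]) * spacing
                       + rng.uniform(-1e-3, 1e-3, 3))
                atoms.append(_mk_atom(serial, "CA", "GLY", ("A", serial, ""),
                                      "C", xyz))
    st = Structure(atoms=atoms, side_a=frozenset("A"))
    if len(st) == 1:
        return st, np.zeros(1)
    levels = bf.reference_pipeline_levels(st)
    return st, levels


@dataclass(frozen=True)
class PlantedResidue:
    """One planted residue: (contact type, burial band, count) triples.

    Band is 0, 1, 2 or 3 (3 meaning 'at least 3').  Per residue at most one
    Type-I and one Type-II entry and up to three Type-III entries are
    realisable, each with at most 6 contacts (one planted site atom serves
    one (type, band) entry; partners sit on up to six axis directions).
    """

    resnum: int
    contacts: tuple[tuple[str, int, int], ...]


@dataclass(frozen=True)
class FixtureSpec:
    """Toy-complex recipe: planted residues plus generator knobs."""

    plants: tuple[PlantedResidue, ...]
    seed: int = 0
    validate: bool = True


def _solid_ball(center: np.ndarray, radius: float, keepout: np.ndarray,
                rng) -> list[np.ndarray]:
    """Deterministically jittered cubic-lattice ball, avoiding planted atoms."""
    if radius <= 0:
        return []
    pts = []
    n = int(np.ceil(radius / _LATTICE_SPACING))
    for ix in range(-n, n + 1):
        for iy in range(-n, n + 1):
            for iz in range(-n, n + 1):
                p = center + np.array([ix, iy, iz]) * _LATTICE_SPACING
                p = p + rng.uniform(-0.25, 0.25, 3)
                if np.linalg.norm(p - center) > radius:
                    continue
                if len(keepout) and np.min(
                        np.linalg.norm(keepout - p, axis=1)) < _CLASH:
                    continue
                pts.append(p)
    return pts


def _inline_type(classes_a, classes_b) -> str:
    # independent re-statement of the typing rules for validation only
    if (POSITIVE in classes_a and NEGATIVE in classes_b) or \
            (POSITIVE in classes_b and NEGATIVE in classes_a):
        return "I"
    if (DONOR in classes_a and ACCEPTOR in classes_b) or \
            (DONOR in classes_b and ACCEPTOR in classes_a):
        return "II"
    return "III"


def _expected_column(ctype: str, band: int) -> str:
    if ctype == "I" and band >= 2:
        return "C_I_ge2"
    return f"C_{ctype}_{'ge3' if band >= 3 else band}"


def make_toy_complex(spec: FixtureSpec
                     ) -> tuple[Structure, dict[tuple, dict[str, int]]]:
    """Two-chain complex with planted typed contacts at known burial bands.

    Returns the structure and, per planted residue id, the expected
    directly-broken interfacial contact counts keyed by feature column name
    (all twelve count columns).  With ``spec.validate`` the construction is
    checked against the independent brute-force pipeline and a ``ValueError``
    is raised if the requested composition was not achieved.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    serial = [0]
    expected: dict[tuple, dict[str, int]] = {}

    def add(name, resname, rid, element, xyz):
        serial[0] += 1
        atoms.append(_mk_atom(serial[0], name, resname, rid, element, xyz))

    partner_num = 0
    filler_num = 5000
    for r_i, plant in enumerate(spec.plants):
        rid = ("A", plant.resnum, "")
        counts = {c: 0 for c in AC_COLUMNS if c != "RBL"}
        used_sites: dict[str, int] = {"I": 0, "II": 0, "III": 0}
        site_index = 0
        for ctype, band, count in plant.contacts:
            if ctype not in _SITE_ATOMS:
                raise ValueError(f"unknown contact type {ctype!r}")
            if band not in BAND_RADII:
                raise ValueError(f"unsupported burial band {band}")
            if count < 0 or count > len(_DIRECTIONS):
                raise ValueError(f"count {count} not realisable (max 6)")
            if used_sites[ctype] >= len(_SITE_ATOMS[ctype]):
                raise ValueError(
                    f"too many {ctype} entries for one residue")
            site_name = _SITE_ATOMS[ctype][used_sites[ctype]]
            used_sites[ctype] += 1
            center = np.array([40.0 * site_index, 60.0 * r_i, 0.0])
            site_index += 1
            element = "N" if site_name.startswith("N") else "C"
            add(site_name, "HIS", rid, element, center)
            pnames, presname = _PARTNER[ctype]
            planted_xyz = [center]
            for k in range(count):
                partner_num += 1
                p = center + _PAIR_DIST * _DIRECTIONS[k]
                planted_xyz.append(p)
                add(pnames, presname, ("B", partner_num, ""),
                    "O" if pnames.startswith("O") else "C", p)
            for p in _solid_ball(center, BAND_RADII[band],
                                 np.asarray(planted_xyz), rng):
                filler_num += 1
                add("CA", "GLY", ("A", filler_num, ""), "C", p)
            counts[_expected_column(ctype, band)] += count
        # exposed backbone clump, away from every site
        base = np.array([-40.0, 60.0 * r_i, 0.0])
        for k, bb in enumerate(["N", "CA", "C", "O", "CB"]):
            add(bb, "HIS", rid, "N" if bb == "N" else
                ("O" if bb == "O" else "C"),
                base + [3.5 * k, 1.2 * (k % 2), 0.9 * ((k + 1) % 2)])
        expected[rid] = counts

    st = Structure(atoms=atoms, side_a=frozenset("A"), side_b=frozenset("B"))
    if spec.validate:
        _validate_toy_complex(st, expected)
    return st, expected


def _validate_toy_complex(st: Structure, expected) -> None:
    """Check planted counts against the brute-force reference pipeline."""
    levels = bf.reference_pipeline_levels(st)
    edges = bf.reference_contact_edges(st)
    for rid, want in expected.items():
        got = {c: 0 for c in want}
        for i, j in edges:
            a, b = st.atoms[i], st.atoms[j]
            for mine, other in ((a, b), (b, a)):
                if (mine.residue_id == rid
                        and mine.name not in ALANINE_REMAINDER
                        and not other.is_water
                        and other.chain in st.side_b):
                    lv = min(levels[i], levels[j])
                    got[_expected_column(
                        _inline_type(mine.chem_classes, other.chem_classes),
                        int(lv))] += 1
        if got != want:
            raise ValueError(
                f"unrealisable composition for residue {rid}: "
                f"wanted {want}, construction gives {got}")


#: Direction of class separation in DBAC feature space (unit-free weights).
_SEP_WEIGHTS = np.array([0.5, 0.4, 0.4, 0.3, 0.6, 0.5])
_NEG_CENTROID = np.array([0.5, 0.2, 0.1, 0.05, 0.5, 0.3])


def make_feature_dataset(n_pos: int, n_neg: int, separation: float,
                         seed: int = 0
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Labelled 6-column DBAC-style feature table with planted separation.

    Negatives scatter around a near-zero centroid, positives around a
    centroid shifted by ``separation`` (in units of the unit-variance noise)
    along an elevated burial-level / deep-count direction.  Count columns
    are rounded to integers and clipped at zero; the burial-level column
    stays real-valued but non-negative.
    """
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 records per class")
    rng = np.random.default_rng(seed)
    pos = (_NEG_CENTROID + separation * _SEP_WEIGHTS
           + rng.normal(0.0, 1.0, (n_pos, 6)))
    neg = _NEG_CENTROID + rng.normal(0.0, 1.0, (n_neg, 6))
    x = np.vstack([pos, neg])
    x[:, 0] = np.clip(x[:, 0], 0.0, None)          # RBL: real, >= 0
    x[:, 1:] = np.clip(np.round(x[:, 1:]), 0, None)  # counts: integers
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    df = pd.DataFrame(x, columns=DBAC_COLUMNS)
    return df, labels
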