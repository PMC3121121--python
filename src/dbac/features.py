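"""Typed interfacial contacts and the DBAC / AC feature vectors.

An *interfacial* contact joins two protein atoms on opposite sides of the
chain partition (waters carry no side and never count as partners; they
influence features only by deepening burial levels).  A contact of a residue
is *directly broken* by mutation to alanine when the residue-side endpoint is
a side-chain atom beyond C-beta — i.e. an atom removed by the substitution;
the partner may be any atom of the other side, backbone included.

Contacts are typed with precedence I > II > III:

* Type I  — one endpoint positively charged, the other negatively charged
  (salt-bridge-like);
* Type II — one endpoint a hydrogen-bond donor, the other an acceptor
  (hydrogen-bond-like);
* Type III — everything else.

Feature vectors count a residue's directly broken interfacial contacts per
type and burial band.  The DBAC set keeps only deeply buried contacts
(burial level >= 2): ``C(I,>=2), C(II,2), C(II,>=3), C(III,2), C(III,>=3)``
plus the residue burial level.  The AC set adds the exposed (level 0) and
slightly buried (level 1) bands for all three types.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .burial import BurialAssignment, ContactGraph, contact_burial_level
from .structure import (ACCEPTOR, ALANINE_REMAINDER, DONOR, NEGATIVE,
                        POSITIVE, ResidueId, Structure)

DBAC_COLUMNS = ["RBL", "C_I_ge2", "C_II_2", "C_II_ge3", "C_III_2", "C_III_ge3"]
AC_EXTRA_COLUMNS = ["C_I_0", "C_I_1", "C_II_0", "C_II_1", "C_III_0", "C_III_1"]
AC_COLUMNS = DBAC_COLUMNS + AC_EXTRA_COLUMNS


@dataclass(frozen=True)
class TypedContact:
    """One atomic contact with its interface status, type and burial level."""

    atoms: tuple[int, int]
    interfacial: bool
    contact_type: str  # "I" | "II" | "III"
    burial_level: int


def classify_contact(classes_a: frozenset[str],
                     classes_b: frozenset[str]) -> str:
    """Type a contact from its endpoints' chemistry classes (I > II > III)."""
    if ((POSITIVE in classes_a and NEGATIVE in classes_b)
            or (NEGATIVE in classes_a and POSITIVE in classes_b)):
        return "I"
    if ((DONOR in classes_a and ACCEPTOR in classes_b)
            or (ACCEPTOR in classes_a and DONOR in classes_b)):
        return "II"
    return "III"


def interfacial_contacts(graph: ContactGraph) -> list[tuple[int, int]]:
    """Edges whose endpoints lie on opposite sides of the partition."""
    st = graph.structure
    st.require_partition()
    out = []
    for i, j in graph.edges:
        si, sj = st.side_of(st.atoms[i]), st.side_of(st.atoms[j])
        if si is None or sj is None:  # water or unpartitioned chain
            continue
        if si != sj:
            out.append((int(i), int(j)))
    return out


def directly_broken_contacts(structure: Structure, residue_id: ResidueId,
                             contacts: list[tuple[int, int]]
                             ) -> list[tuple[int, int]]:
    """The residue's interfacial contacts lost by pure atom removal.

    Keeps contacts whose residue-side endpoint is a side-chain atom beyond
    C-beta (name not in N, CA, C, O, CB, OXT).  Returned pairs are ordered
    (residue atom, partner atom).
    """
    structure.residue_atoms(residue_id)  # raises KeyError if absent
    out = []
    for i, j in contacts:
        for mine, partner in ((i, j), (j, i)):
            a = structure.atoms[mine]
            if (a.residue_id == residue_id
                    and a.name not in ALANINE_REMAINDER):
                out.append((mine, partner))
                break
    return out


def typed_contacts(structure: Structure, assignment: BurialAssignment,
                   residue_id: ResidueId) -> list[TypedContact]:
    """All directly broken interfacial contacts of one residue, typed."""
    graph = assignment.graph
    inter = interfacial_contacts(graph)
    out = []
    for mine, partner in directly_broken_contacts(structure, residue_id, inter):
        a, b = structure.atoms[mine], structure.atoms[partner]
        out.append(TypedContact(
            atoms=(mine, partner),
            interfacial=True,
            contact_type=classify_contact(a.chem_classes, b.chem_classes),
            burial_level=contact_burial_level(assignment, (mine, partner)),
        ))
    return out


def _band(level: int) -> str:
    if level >= 3:
        return "ge3"
    return str(level)


def feature_vector(structure: Structure, assignment: BurialAssignment,
                   residue_id: ResidueId, mode: str = "DBAC") -> pd.Series:
    """DBAC (6 values) or AC (12 values) feature vector of one residue."""
    mode = mode.upper()
    if mode not in ("DBAC", "AC"):
        raise ValueError(f"unknown feature mode {mode!r}")
    counts = {c: 0 for c in AC_COLUMNS if c != "RBL"}
    for tc in typed_contacts(structure, assignment, residue_id):
        t, band = tc.contact_type, _band(tc.burial_level)
        if t == "I" and band in ("2", "ge3"):
            band = "ge2"  # Type I merges the deep bands
        counts[f"C_{t}_{band}"] += 1
    cols = DBAC_COLUMNS if mode == "DBAC" else AC_COLUMNS
    values = {"RBL": assignment.residue_level(residue_id)}
    values.update({c: counts[c] for c in cols if c != "RBL"})
    return pd.Series(values, index=cols, name=residue_id)


def feature_table(structure: Structure, assignment: BurialAssignment,
                  residue_ids: list[ResidueId] | None = None,
                  mode: str = "DBAC") -> pd.DataFrame:
    """Feature vectors for many residues as a DataFrame (one row each)."""
    if residue_ids is None:
        residue_ids = interface_residues(structure, assignment.graph)
    rows = [feature_vector(structure, assignment, rid, mode)
            for rid in residue_ids]
    df = pd.DataFrame(rows)
    df.index = pd.Index(residue_ids, name="residue")
    return df


def interface_residues(structure: Structure,
                       graph: ContactGraph) -> list[ResidueId]:
    """Residues with at least one interfacial atomic contact."""
    inter = interfacial_contacts(graph)
    seen: set[ResidueId] = set()
    order: list[ResidueId] = []
    for i, j in inter:
        for k in (i, j):
            rid = structure.atoms[k].residue_id
            if rid not in seen:
                seen.add(rid)
                order.append(rid)
    return order
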