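"""Shared fixtures: hand-written PDB snippets and cached synthetic complexes."""

from __future__ import annotations

import numpy as np
import pytest

from dbac.burial import atom_burial_levels, build_contact_graph
from dbac.sasa import solvate_and_label
from dbac.structure import Atom, Structure, default_tables
from dbac.synthetic import FixtureSpec, PlantedResidue, make_toy_complex

ALA_HOH_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.331  -5.830  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.530   6.248  -4.103  1.00  0.00           C
ATOM      6  HA  ALA A   1      12.110   5.098  -5.022  1.00  0.00           H
HETATM    7  O   HOH A 101      15.000   8.000  -3.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   SER A   1       3.200   1.600   0.000  1.00  0.00           O
ATOM      5  CB  SER A   1       1.900  -0.800   1.200  1.00  0.00           C
ATOM      6  OG ASER A   1       1.500  -2.100   1.300  0.60  0.00           O
ATOM      7  OG BSER A   1       3.300  -0.900   1.400  0.40  0.00           O
END
"""


def make_atom(i, name, resname, rid, element, xyz, is_water=False):
    tables = default_tables()
    return Atom(serial=i, name=name, residue_name=resname, residue_id=rid,
                element=element, coords=tuple(float(v) for v in xyz),
                is_water=is_water,
                vdw_radius=tables.vdw_radius(element, is_water),
                chem_classes=tables.chem_classes(resname, name, is_water))


def carbon_cloud(n, seed=0, scale=12.0):
    """Structure of n carbon atoms scattered in a cube (single chain)."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, scale, size=(n, 3))
    atoms = [make_atom(i + 1, "CA", "GLY", ("A", i + 1, ""), "C", p)
             for i, p in enumerate(pts)]
    return Structure(atoms=atoms, side_a=frozenset("A"))


@pytest.fixture
def ala_hoh_pdb(tmp_path):
    p = tmp_path / "ala_hoh.pdb"
    p.write_text(ALA_HOH_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture(scope="session")
def toy_mixed():
    """One planted residue mixing types and bands, validated at build time."""
    spec = FixtureSpec(plants=(
        PlantedResidue(10, (("I", 2, 2), ("II", 2, 3), ("III", 2, 4),
                            ("III", 3, 2))),
        PlantedResidue(11, (("II", 0, 2), ("III", 1, 3))),
    ), seed=7)
    return make_toy_complex(spec)


@pytest.fixture(scope="session")
def toy_mixed_pipeline(toy_mixed):
    """Production pipeline products for the mixed toy complex."""
    st, expected = toy_mixed
    pruned, flags, _ = solvate_and_label(st)
    graph = build_contact_graph(pruned, flags)
    assignment = atom_burial_levels(graph)
    return pruned, graph, assignment, expected
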