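"""Independent brute-force reference pipeline for fixture validation.

Everything here recomputes quantities of the main pipeline by a different
route and shares no code with it:

* SASA via Biopython's Shrake-Rupley implementation (its own sphere mesh),
* Delaunay neighbour pairs enumerated directly from simplex vertex lists,
* contact edges by an O(n^2) double loop over atom pairs,
* burial levels as the minimum over exposed atoms of per-source
  breadth-first distances in a networkx graph.

These references back the generators in :mod:`dbac.synthetic` and the test
suite; they are deliberately slow and only meant for small fixtures.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay

from .structure import Structure


def reference_sasa(structure: Structure, probe_radius: float = 1.4,
                   n_points: int = 960) -> np.ndarray:
    """Per-atom SASA via Bio.PDB's Shrake-Rupley (independent mesh/code)."""
    import warnings

    from Bio.PDB.PDBExceptions import PDBConstructionWarning
    from Bio.PDB.SASA import ShrakeRupley
    from Bio.PDB.StructureBuilder import StructureBuilder

    warnings.simplefilter("ignore", PDBConstructionWarning)
    b = StructureBuilder()
    b.init_structure("x")
    b.init_model(0)
    b.init_seg("    ")
    serial = 0
    chain_open = None
    for i, a in enumerate(structure.atoms):
        chain = a.residue_id[0] or "W"
        if chain != chain_open:
            b.init_chain(chain)
            chain_open = chain
        field = "W" if a.is_water else " "
        b.init_residue(a.residue_name, field, i + 1, " ")  # unique residues
        serial += 1
        b.init_atom(a.name, np.array(a.coords), 0.0, 1.0, " ",
                    a.name.center(4), serial, element=a.element)
    struct = b.get_structure()
    radii = {a.element.upper(): a.vdw_radius for a in structure.atoms}
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points,
                      radii_dict=radii)
    sr.compute(struct, level="A")
    # one single-atom residue per input atom; its seq id encodes the index
    out = np.full(len(structure), np.nan)
    for at in struct.get_atoms():
        out[at.get_parent().get_id()[1] - 1] = at.sasa
    assert not np.isnan(out).any()
    return out


def reference_delaunay_pairs(points: np.ndarray) -> set[tuple[int, int]]:
    """Neighbour pairs read straight off the simplex list."""
    tri = Delaunay(np.asarray(points, dtype=float))
    pairs: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i, j in combinations(sorted(int(v) for v in simplex), 2):
            pairs.add((i, j))
    return pairs


def reference_contact_edges(structure: Structure,
                            pad: float = 2.75) -> set[tuple[int, int]]:
    """{Delaunay pairs} intersected with {distance-gated pairs}, brute force."""
    pts = structure.coords()
    radii = structure.radii()
    edges = set()
    for i, j in reference_delaunay_pairs(pts):
        d = math.dist(pts[i], pts[j])
        if d < radii[i] + radii[j] + pad:
            edges.add((i, j))
    return edges


def reference_burial_levels(n_atoms: int, edges: set[tuple[int, int]],
                            exposed: np.ndarray) -> np.ndarray:
    """Min over exposed sources of BFS distance; inf when unreachable."""
    g = nx.Graph()
    g.add_nodes_from(range(n_atoms))
    g.add_edges_from(edges)
    levels = np.full(n_atoms, np.inf)
    for src in np.flatnonzero(np.asarray(exposed, dtype=bool)):
        for node, d in nx.single_source_shortest_path_length(g, int(src)).items():
            levels[node] = min(levels[node], d)
    return levels


def reference_pipeline_levels(structure: Structure,
                              probe_radius: float = 1.4,
                              threshold: float = 10.0,
                              pad: float = 2.75) -> np.ndarray:
    """Full independent pipeline: SASA -> exposure -> edges -> BFS levels.

    Assumes the structure is already water-pruned (or water-free).
    """
    areas = reference_sasa(structure, probe_radius)
    exposed = areas >= threshold
    edges = reference_contact_edges(structure, pad)
    return reference_burial_levels(len(structure), edges, exposed)
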