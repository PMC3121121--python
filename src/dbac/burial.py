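"""Atomic contact graph and burial levels.

Two heavy atoms are *in contact* when they satisfy both gates:

1. they are Delaunay neighbours — their Voronoi cells share a facet, so no
   third atom sits between them; and
2. their centre distance is strictly less than ``r_i + r_j + 2.75`` A, the
   two van der Waals radii plus the diameter of a water molecule.

The *burial level* of an atom is the length of the shortest contact-graph
path from the atom to its nearest exposed atom (exposed atoms are level 0).
It is computed by attaching a pseudo node standing for bulk solvent to every
exposed atom and running a unit-weight single-source shortest path from it
(BFS; identical to Dijkstra on unit weights), then subtracting one.  Buried
waters take part as ordinary nodes.  A residue's burial level is the mean
over its heavy atoms; a contact's burial level is the smaller of its two
endpoint levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import Delaunay

from .structure import ResidueId, Structure

log = logging.getLogger(__name__)

WATER_DIAMETER = 2.75  # A, contact-gate pad

UNREACHABLE = math.inf


@dataclass
class ContactGraph:
    """Undirected atomic contact graph with exposure flags.

    ``edges`` is an (m, 2) int array with ``edges[:, 0] < edges[:, 1]``,
    sorted lexicographically; ``exposed`` aligns with the structure's atoms.
    The bulk-solvent pseudo node is implicit: it connects to exactly the
    exposed atoms and is materialised only inside the shortest-path solve.
    """

    structure: Structure
    edges: np.ndarray
    exposed: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.exposed = np.asarray(self.exposed, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.structure)

    def adjacency(self) -> sparse.csr_matrix:
        n = self.n_atoms
        if len(self.edges) == 0:
            return sparse.csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(len(self.edges))
        m = sparse.coo_matrix((data, (i, j)), shape=(n, n))
        return (m + m.T).tocsr()

    def edge_set(self) -> set[tuple[int, int]]:
        return {tuple(e) for e in self.edges}


@dataclass
class BurialAssignment:
    """Burial levels of atoms (int, inf sentinel when unreachable)."""

    graph: ContactGraph
    atom_level: np.ndarray  # float array; integral values or inf

    def residue_level(self, residue_id: ResidueId) -> float:
        return residue_burial_level(self, residue_id)

    def contact_level(self, edge: tuple[int, int]) -> int:
        return contact_burial_level(self, edge)

    @property
    def max_level(self) -> int:
        finite = self.atom_level[np.isfinite(self.atom_level)]
        return int(finite.max()) if len(finite) else 0


def _delaunay_pairs(points: np.ndarray) -> set[tuple[int, int]]:
    tri = Delaunay(points)
    indptr, indices = tri.vertex_neighbor_vertices
    pairs: set[tuple[int, int]] = set()
    for i in range(len(points)):
        for j in indices[indptr[i]:indptr[i + 1]]:
            if i < j:
                pairs.add((i, int(j)))
    return pairs


def build_contact_graph(structure: Structure, exposed: np.ndarray,
                        pad: float = WATER_DIAMETER,
                        jitter: float = 0.0,
                        jitter_seed: int = 0) -> ContactGraph:
    """Contact graph of a (water-pruned) structure.

    ``exposed`` are the exposure flags aligned to the structure's atoms.
    ``jitter`` optionally perturbs coordinates (uniform +-jitter A, seeded)
    before triangulation to break exactly degenerate geometries.
    """
    n = len(structure)
    if n < 5:
        raise ValueError("need at least 5 atoms for a 3D triangulation")
    exposed = np.asarray(exposed, dtype=bool)
    if len(exposed) != n:
        raise ValueError("exposure flags do not match structure")
    pts = structure.coords()
    if jitter:
        rng = np.random.default_rng(jitter_seed)
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    try:
        pairs = _delaunay_pairs(pts)
    except Exception as exc:  # qhull degeneracy
        raise ValueError(
            "Delaunay triangulation failed (degenerate geometry?); "
            "retry with jitter > 0"
        ) from exc
    radii = structure.radii()
    edges = []
    for i, j in sorted(pairs):
        d = float(np.linalg.norm(pts[i] - pts[j]))
        if d < radii[i] + radii[j] + pad:  # strict: the boundary is no contact
            edges.append((i, j))
    edges_arr = (np.asarray(edges, dtype=int) if edges
                 else np.empty((0, 2), dtype=int))
    return ContactGraph(structure=structure, edges=edges_arr, exposed=exposed)


def atom_burial_levels(graph: ContactGraph) -> BurialAssignment:
    """Shortest unit-weight path from the bulk-solvent pseudo node, minus 1."""
    n = graph.n_atoms
    exp_idx = np.flatnonzero(graph.exposed)
    if len(exp_idx) == 0:
        raise ValueError("no exposed atoms: burial levels undefined")
    # adjacency extended with the pseudo node at index n
    rows = [graph.edges[:, 0], graph.edges[:, 1],
            np.full(len(exp_idx), n), exp_idx]
    cols = [graph.edges[:, 1], graph.edges[:, 0],
            exp_idx, np.full(len(exp_idx), n)]
    data = np.ones(2 * len(graph.edges) + 2 * len(exp_idx))
    adj = sparse.csr_matrix(
        (data, (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 1, n + 1))
    dist = dijkstra(adj, unweighted=True, indices=n)
    levels = dist[:n] - 1.0
    levels[exp_idx] = 0.0
    if np.isinf(levels).any():
        log.warning("%d atoms unreachable from any exposed atom",
                    int(np.isinf(levels).sum()))
    return BurialAssignment(graph=graph, atom_level=levels)


def residue_burial_level(assignment: BurialAssignment,
                         residue_id: ResidueId) -> float:
    """Mean burial level over a residue's heavy atoms (backbone included)."""
    idx = assignment.graph.structure.residue_atoms(residue_id)
    lv = assignment.atom_level[idx]
    finite = lv[np.isfinite(lv)]
    if len(finite) == 0:
        raise ValueError(f"residue {residue_id} has no reachable atoms")
    if len(finite) < len(lv):
        log.warning("residue %s: %d unreachable atoms excluded from mean",
                    residue_id, len(lv) - len(finite))
    return float(finite.mean())


def contact_burial_level(assignment: BurialAssignment,
                         edge: tuple[int, int]) -> int:
    """Burial level of a contact: the smaller of its endpoint levels."""
    a, b = assignment.atom_level[edge[0]], assignment.atom_level[edge[1]]
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError(f"contact {edge} touches an unreachable atom")
    return int(min(a, b))
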