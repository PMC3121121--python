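"""Per-atom solvent accessible surface area and exposure labeling.

SASA is computed with the Shrake-Rupley point-sampling method: each atom is
inflated by the probe radius (default 1.4 A) and covered with a deterministic
golden-spiral mesh of test points; the accessible area is the fraction of
points not swallowed by any neighbouring inflated sphere.  An atom whose SASA
is at least 10 A^2 is labelled EXPOSED, otherwise BURIED; the same threshold
decides which crystallographic waters count as bulk solvent and are removed
before the contact graph is built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure, drop_atoms

EXPOSURE_THRESHOLD = 10.0  # A^2; boundary inclusive ("not less than")
DEFAULT_PROBE = 1.4        # A
DEFAULT_N_POINTS = 960


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere mesh (golden spiral)."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    """Per-atom areas (A^2, aligned to structure atom order) and flags."""

    areas: np.ndarray
    probe_radius: float
    threshold: float
    exposed: np.ndarray  # bool, EXPOSED iff area >= threshold

    def __len__(self) -> int:
        return len(self.areas)

    @property
    def total(self) -> float:
        return float(self.areas.sum())


def compute_sasa(structure: Structure,
                 probe_radius: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS,
                 threshold: float = EXPOSURE_THRESHOLD) -> SasaResult:
    """Shrake-Rupley SASA over every atom present (protein and waters)."""
    if len(structure) == 0:
        raise ValueError("empty structure")
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    xyz = structure.coords()
    radii = structure.radii() + probe_radius
    n = len(xyz)
    mesh = _sphere_points(n_points)

    tree = cKDTree(xyz)
    # any pair closer than the sum of the two largest inflated radii can occlude
    pairs = tree.query_ball_tree(tree, r=2.0 * radii.max())
    areas = np.empty(n)
    for i in range(n):
        pts = xyz[i] + radii[i] * mesh
        accessible = np.ones(n_points, dtype=bool)
        for j in pairs[i]:
            if j == i:
                continue
            if np.linalg.norm(xyz[j] - xyz[i]) >= radii[i] + radii[j]:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 >= radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return SasaResult(areas=areas, probe_radius=probe_radius,
                      threshold=threshold,
                      exposed=label_exposure(areas, threshold))


def label_exposure(areas: np.ndarray,
                   threshold: float = EXPOSURE_THRESHOLD) -> np.ndarray:
    """EXPOSED (True) iff SASA >= threshold; the boundary is exposed."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return np.asarray(areas) >= threshold


def prune_exposed_waters(structure: Structure,
                         result: SasaResult) -> tuple[Structure, np.ndarray]:
    """Remove exposed waters (bulk solvent); keep buried waters and protein.

    Returns the pruned structure and the indices (into the original atom
    order) of the retained atoms, so exposure flags can be carried over.
    """
    if len(result.areas) != len(structure):
        raise ValueError("SASA result does not match structure")
    water = structure.water_mask()
    remove = np.flatnonzero(water & result.exposed)
    kept = np.setdiff1d(np.arange(len(structure)), remove)
    return drop_atoms(structure, remove.tolist()), kept


def read_naccess_asa(path) -> np.ndarray:
    """Per-atom areas from a NACCESS ``.asa`` file, in file order.

    NACCESS writes PDB-like records with the accessible area in the
    occupancy column; this reader exists for bit-compatibility comparisons
    against externally computed areas.
    """
    areas = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                areas.append(float(line[54:62]))
    if not areas:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return np.asarray(areas)


def solvate_and_label(structure: Structure,
                      probe_radius: float = DEFAULT_PROBE,
                      threshold: float = EXPOSURE_THRESHOLD,
                      n_points: int = DEFAULT_N_POINTS,
                      recompute_after_prune: bool = False
                      ) -> tuple[Structure, np.ndarray, SasaResult]:
    """One-shot convenience: SASA on the full complex, prune exposed waters.

    By default a single SASA pass supplies both the water pruning and the
    exposure flags of the remaining atoms.  With ``recompute_after_prune``
    the flags are re-derived from a second SASA pass on the pruned complex
    (sensitivity-analysis mode).

    Returns ``(pruned structure, exposure flags aligned to it, full-pass SASA)``.
    """
    full = compute_sasa(structure, probe_radius, n_points, threshold)
    pruned, kept = prune_exposed_waters(structure, full)
    if recompute_after_prune:
        second = compute_sasa(pruned, probe_radius, n_points, threshold)
        return pruned, second.exposed, full
    return pruned, full.exposed[kept], full
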