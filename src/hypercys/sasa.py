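"""Solvent-accessible surface area and burial depth.

Shrake-Rupley SASA with a deterministic golden-spiral point lattice: each
atom is covered with ``n_sphere_points`` quasi-uniform points at radius
(vdw + probe); points falling inside any neighboring atom's probe-expanded
sphere are occluded.  Determinism (no Monte-Carlo sampling) makes every
downstream feature byte-reproducible.

Burial depth of a cysteine is the distance from its sulfur (fallback CB,
then CA) to the nearest accessible surface point, corrected for the probe
shell so that a fully exposed sulfur has depth ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, CysteineSite, ProteinStructure

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n quasi-uniform unit vectors."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SASAResult:
    atom_sasa: dict[int, float]                    # atom serial -> A^2
    residue_sasa: dict[tuple[str, int], float]     # (chain, resnum) -> A^2
    accessible_points: np.ndarray                  # (M, 3) surface points
    probe_radius: float
    n_sphere_points: int


def compute_sasa(
    structure: ProteinStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    include_hetero: bool = False,
    rotation: np.ndarray | None = None,
) -> SASAResult:
    """Per-atom and per-residue SASA via the Shrake-Rupley algorithm.

    ``rotation`` optionally rotates the point lattice together with the
    molecule (a 3x3 orthogonal matrix), which makes total SASA exactly
    invariant under that same rotation of the coordinates.
    """
    atoms = [a for a in structure.atoms if include_hetero or not a.is_hetero]
    atoms = [a for a in atoms if a.element != "H"]
    if not atoms:
        raise ValueError("structure has no atoms for SASA computation")

    xyz = np.array([a.position for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    unit = sphere_points(n_sphere_points)
    if rotation is not None:
        unit = unit @ np.asarray(rotation, dtype=float).T

    tree = cKDTree(xyz)
    max_radius = radii.max()

    atom_sasa: dict[int, float] = {}
    residue_sasa: dict[tuple[str, int], float] = {}
    accessible: list[np.ndarray] = []

    for i, atom in enumerate(atoms):
        pts = xyz[i] + radii[i] * unit
        # Any atom whose expanded sphere can reach this one is a candidate
        # occluder.
        nbr_idx = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_radius)
                   if j != i]
        exposed = np.ones(len(pts), dtype=bool)
        for j in nbr_idx:
            d = np.linalg.norm(pts - xyz[j], axis=1)
            exposed &= d >= radii[j]
        frac = exposed.mean()
        area = 4.0 * np.pi * radii[i] ** 2 * frac
        atom_sasa[atom.serial] = float(area)
        key = (atom.chain, atom.residue_number)
        residue_sasa[key] = residue_sasa.get(key, 0.0) + float(area)
        if exposed.any():
            accessible.append(pts[exposed])

    # Residues may be absent from residue_sasa only if they had no heavy
    # atoms; ensure every residue of the structure has an entry.
    for atom in atoms:
        residue_sasa.setdefault((atom.chain, atom.residue_number), 0.0)

    points = np.vstack(accessible) if accessible else np.empty((0, 3))
    return SASAResult(
        atom_sasa=atom_sasa,
        residue_sasa=residue_sasa,
        accessible_points=points,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )


def _depth_anchor(structure: ProteinStructure, site: CysteineSite) -> Atom:
    atoms = structure.residue_atoms(site.chain, site.residue_number)
    for name in ("SG", "CB", "CA"):
        for a in atoms:
            if a.name == name:
                return a
    raise ValueError(
        f"no SG/CB/CA anchor atom for site {site.chain}:{site.residue_number}"
    )


def residue_depth(
    structure: ProteinStructure,
    site: CysteineSite,
    sasa: SASAResult,
) -> float:
    """Burial depth (A) of the cysteine sulfur below the accessible surface.

    depth = max(0, min ||anchor - p|| - (r_anchor + probe)) over accessible
    surface points p, so an exposed sulfur whose own sphere points survive
    occlusion reports depth 0.
    """
    if sasa.accessible_points.shape[0] == 0:
        raise ValueError("structure has no solvent-exposed atoms")
    anchor = _depth_anchor(structure, site)
    dmin = float(np.min(np.linalg.norm(sasa.accessible_points - anchor.position, axis=1)))
    return max(0.0, dmin - (anchor.vdw_radius + sasa.probe_radius))
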