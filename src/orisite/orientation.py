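"""Side-chain orientation geometry and grid-based active-site scanning.

The structure is embedded in a 30x30x30 grid spanning the Cα bounding box.
Each grid point is a candidate catalytic-site center.  For a point *i* and a
vector-bearing surrounding residue *j* (Cα within 10 Å), the angle θ_ij
between the Cα→point vector and the residue's side-chain vector measures how
directly the side chain aims at the point.  Points keep only if at least
three surrounding residues exist and their mean angle is at most 80°;
surviving points seed the triplet scoring stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateStructureError, UndefinedAngleError
from .structure_io import Residue, Structure

logger = logging.getLogger(__name__)

GRID_POINTS_DEFAULT = 30
RADIUS_A_DEFAULT = 10.0
THETA_CUTOFF_DEG_DEFAULT = 80.0
MIN_SURROUNDING_DEFAULT = 3
#: per-axis floor on grid spacing, Å (guards degenerate/flat bounding boxes)
MIN_SPACING_A = 0.5


@dataclass(frozen=True)
class SideChainVector:
    """Un-normalized side-chain direction of one residue: vector-atom
    position minus Cα position, Å."""

    residue_index: int  # index into Structure.residues
    residue: Residue
    vector: np.ndarray

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector))


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned regular grid: origin (Å), per-axis spacing (Å), points
    per axis (inclusive of both faces)."""

    origin: np.ndarray
    spacing: np.ndarray
    points_per_axis: int = GRID_POINTS_DEFAULT

    def coordinates(self) -> np.ndarray:
        """All grid-point positions, shape (points_per_axis**3, 3)."""
        n = self.points_per_axis
        axes = [self.origin[d] + self.spacing[d] * np.arange(n) for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class CandidatePoint:
    """A surviving grid point: its position, the surrounding vector-bearing
    residues (indices into ``Structure.residues``), their θ angles (deg) and
    the mean angle."""

    position: np.ndarray
    surrounding: list[int]
    thetas: np.ndarray
    mean_theta: float

    @property
    def n_surrounding(self) -> int:
        return len(self.surrounding)


def side_chain_vectors(structure: Structure) -> list[SideChainVector]:
    """One side-chain vector per vector-bearing residue.

    Residues whose designated vector atom is missing, or coincides with the
    Cα (zero-length vector), are excluded with a warning.
    """
    out: list[SideChainVector] = []
    for idx, res in enumerate(structure.residues):
        if not res.has_sidechain_vector:
            continue
        vec = res.vector_atom_position - res.ca
        if np.linalg.norm(vec) <= 0.0:
            logger.warning("residue %s: vector atom coincides with CA; excluded",
                           res.label)
            continue
        out.append(SideChainVector(residue_index=idx, residue=res, vector=vec))
    return out


def build_grid(structure: Structure, points_per_axis: int = GRID_POINTS_DEFAULT) -> GridSpec:
    """Grid spanning the Cα bounding box, ``points_per_axis`` points per axis.

    Per-axis spacing is extent/(points-1), floored at 0.5 Å so flat or
    near-degenerate boxes still get a usable grid.  All Cα coincident raises
    :class:`DegenerateStructureError`.
    """
    ca = structure.ca_coordinates()
    if ca.size == 0:
        raise DegenerateStructureError("structure has no residues")
    lo = ca.min(axis=0)
    hi = ca.max(axis=0)
    extent = hi - lo
    if np.all(extent <= 1e-9):
        raise DegenerateStructureError("all CA atoms coincide; cannot build a grid")
    spacing = np.maximum(extent / (points_per_axis - 1), MIN_SPACING_A)
    return GridSpec(origin=lo, spacing=spacing, points_per_axis=points_per_axis)


def surrounding_residues(
    point: np.ndarray,
    structure: Structure,
    vectors: list[SideChainVector] | None = None,
    radius: float = RADIUS_A_DEFAULT,
) -> list[int]:
    """Indices of vector-bearing residues with ‖Cα − point‖ strictly < radius."""
    if vectors is None:
        vectors = side_chain_vectors(structure)
    point = np.asarray(point, dtype=float)
    out = []
    for sv in vectors:
        if np.linalg.norm(sv.residue.ca - point) < radius:
            out.append(sv.residue_index)
    return out


def angle_theta(point: np.ndarray, ca: np.ndarray, side_chain: np.ndarray) -> float:
    """θ (degrees) between the Cα→point vector and the side-chain vector.

    Clamped into [0°, 180°]; a point coincident with the Cα raises
    :class:`UndefinedAngleError`.
    """
    v = np.asarray(point, dtype=float) - np.asarray(ca, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0.0:
        raise UndefinedAngleError("point coincides with residue CA")
    s = np.asarray(side_chain, dtype=float)
    cosang = float(np.dot(v, s) / (nv * np.linalg.norm(s)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def candidate_points(
    structure: Structure,
    grid: GridSpec | None = None,
    vectors: list[SideChainVector] | None = None,
    radius: float = RADIUS_A_DEFAULT,
    theta_cutoff: float = THETA_CUTOFF_DEG_DEFAULT,
    min_surrounding: int = MIN_SURROUNDING_DEFAULT,
    chunk_size: int = 4096,
) -> list[CandidatePoint]:
    """Scan the grid and keep candidate catalytic-site centers.

    A grid point survives when it has at least ``min_surrounding``
    surrounding residues (vector-bearing, Cα strictly within ``radius``) and
    the arithmetic mean of its θ angles does not exceed ``theta_cutoff``
    (strictly-greater points are removed, so a mean of exactly 80° is kept).
    """
    if vectors is None:
        vectors = side_chain_vectors(structure)
    if grid is None:
        grid = build_grid(structure)
    if not vectors:
        return []

    ca = np.array([sv.residue.ca for sv in vectors])                 # (n, 3)
    s_unit = np.array([sv.vector / sv.norm for sv in vectors])       # (n, 3)
    res_idx = np.array([sv.residue_index for sv in vectors])
    # dot(point - ca_j, s_j) = point . s_j - ca_j . s_j
    ca_dot_s = np.einsum("ij,ij->i", ca, s_unit)                     # (n,)

    points = grid.coordinates()
    out: list[CandidatePoint] = []
    for start in range(0, len(points), chunk_size):
        chunk = points[start:start + chunk_size]                     # (m, 3)
        dist = cdist(chunk, ca)                                      # (m, n)
        within = dist < radius
        counts = within.sum(axis=1)
        rows = np.nonzero(counts >= min_surrounding)[0]
        if rows.size == 0:
            continue
        dots = chunk[rows] @ s_unit.T - ca_dot_s                     # (r, n)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = dots / dist[rows]
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))    # (r, n)
        for r, row in enumerate(rows):
            mask = within[row]
            th = theta[r, mask]
            if not np.all(np.isfinite(th)):  # point sits exactly on a CA
                continue
            mean_theta = float(th.mean())
            if mean_theta > theta_cutoff:
                continue
            out.append(
                CandidatePoint(
                    position=chunk[row],
                    surrounding=list(res_idx[mask]),
                    thetas=th,
                    mean_theta=mean_theta,
                )
            )
    logger.info("grid scan: %d/%d points kept (N>=%d, mean theta<=%g deg)",
                len(out), len(points), min_surrounding, theta_cutoff)
    return out
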