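"""Weighted contact number (WCN) as a proxy for local structural rigidity.

For residue k, w_k = Σ_{m≠k} 1/r_km² over every other residue of the
processed structure, where r_km is the Cα–Cα distance.  High w_k means a
densely packed, rigid neighborhood; catalytic residues tend to sit in such
neighborhoods.  The profile is z-normalized per protein with population
statistics (divide-by-n), the convention used for every normalization in
this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import CoincidentAtomError, DegenerateStructureError, NormalizationError
from .structure_io import Structure


@dataclass
class FlexibilityProfile:
    """Per-residue WCN ``w`` and z-scores ``z``, aligned with
    ``Structure.residues``; ``mean``/``sd`` are the population statistics
    used for the normalization."""

    w: np.ndarray
    z: np.ndarray
    mean: float
    sd: float


def wcn(structure: Structure, normalize: bool = True) -> FlexibilityProfile:
    """Compute the WCN flexibility profile of a structure.

    Requires at least two residues, all with distinct Cα positions.  Raises
    :class:`CoincidentAtomError` naming the offending pair when two Cα
    coincide, and :class:`NormalizationError` when z-scores are requested
    but the WCN values have zero spread (``normalize=False`` returns raw w
    with all-zero z instead, e.g. for perfectly symmetric toy inputs).
    """
    n = len(structure.residues)
    if n < 2:
        raise DegenerateStructureError("WCN needs at least 2 residues")
    ca = structure.ca_coordinates()
    d = pdist(ca)
    if np.any(d == 0.0):
        mat = squareform(d)
        np.fill_diagonal(mat, np.inf)
        k, m = np.unravel_index(np.argmin(mat), mat.shape)
        raise CoincidentAtomError(
            f"residues {structure.residues[k].label} and "
            f"{structure.residues[m].label} have identical CA coordinates"
        )
    inv2 = squareform(1.0 / d**2)
    w = inv2.sum(axis=1)
    mean = float(w.mean())
    sd = float(w.std())  # population SD
    if sd == 0.0:
        if normalize:
            raise NormalizationError("WCN values are constant; z-scores undefined")
        return FlexibilityProfile(w=w, z=np.zeros_like(w), mean=mean, sd=0.0)
    return FlexibilityProfile(w=w, z=(w - mean) / sd, mean=mean, sd=sd)
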