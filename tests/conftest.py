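"""Shared fixtures: in-memory structure builders and random generators."""

from __future__ import annotations

import numpy as np
import pytest

from orisite.aa_profiles import ProfileSet, build_profiles
from orisite.structure_io import (
    SIDECHAIN_VECTOR_ATOMS,
    STANDARD_AA,
    Atom,
    Residue,
    Structure,
)


def make_structure(residue_specs, structure_id="test") -> Structure:
    """Build a Structure from (chain, num, icode, aa, ca, tip_or_None) tuples.

    ``tip`` is the side-chain vector atom position; ``None`` leaves the
    residue without a vector atom.
    """
    residues = []
    for chain, num, icode, aa, ca, tip in residue_specs:
        atoms = {"CA": Atom("CA", np.asarray(ca, dtype=float))}
        if tip is not None:
            name = SIDECHAIN_VECTOR_ATOMS[aa]
            atoms[name] = Atom(name, np.asarray(tip, dtype=float))
        residues.append(Residue(chain, num, icode, aa, atoms))
    return Structure(id=structure_id, residues=residues)


def random_structure(rng: np.random.Generator, n: int = 12,
                     box: float = 25.0) -> Structure:
    """Random small structure: Cα ≥ 3.9 Å apart, random types over all 20,
    vector-bearing ones get a random 1.5–4 Å side-chain vector."""
    cas: list[np.ndarray] = []
    while len(cas) < n:
        cand = rng.uniform(0.0, box, 3)
        if all(np.linalg.norm(cand - c) >= 3.9 for c in cas):
            cas.append(cand)
    specs = []
    for i, ca in enumerate(cas):
        aa = STANDARD_AA[rng.integers(20)]
        tip = None
        if aa in SIDECHAIN_VECTOR_ATOMS:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            tip = ca + rng.uniform(1.5, 4.0) * direction
        specs.append(("A", i + 1, "", aa, ca, tip))
    return make_structure(specs, structure_id="random")


def pdb_atom_line(serial, name, resname, chain, resnum, pos, occ=1.0,
                  altloc=" ", record="ATOM  ", icode=" ") -> str:
    pad = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:5d} {pad}{altloc}{resname:3s} {chain:1s}"
        f"{resnum:4d}{icode}   {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
        f"{occ:6.2f}{0.0:6.2f}          {name[0]:>2s}"
    )


@pytest.fixture
def triad_profiles() -> ProfileSet:
    """Profile built from one Ser-His-Asp site and one Asp-Glu pair."""
    return build_profiles([["ASP", "HIS", "SER"], ["ASP", "GLU"]])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240911)
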