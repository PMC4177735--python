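"""Synthetic PDB fixture generator.

Emits small, syntactically valid PDB structures with a planted "catalytic
site": site residues sit with their Cα on a ring and their side-chain
vector atoms displaced toward the ring center (inward mode — the hallmark
orientation of catalytic residues) or away from it (outward control).
Decoy residues fill a spherical shell outside the site with seeded-random
side-chain directions, emulating the random orientation of noncatalytic
residues.  Geometry is idealized: each residue gets Cα, its designated
side-chain vector atom and dummy N/C/O backbone atoms for format validity —
enough for every computation in this package, with no rotamer realism.

Defaults plant a 3-residue site of classic catalytic types (HIS, ASP, GLU)
on a 3.5 Å ring — Cα–Cα separations of ~6 Å, as in real catalytic triads —
with a 3.5 Å side-chain displacement (a typical Cα→functional-atom reach)
among 24 decoys kept at least 6 Å apart (non-bonded surface packing) in a
shell outside the site sphere (ring radius + the 10 Å surrounding radius);
small seeded positional and angular jitter (0.3 Å / ~0.1 rad) keeps the
geometry realistic rather than exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GenerationError
from .structure_io import SIDECHAIN_VECTOR_ATOMS, STANDARD_AA

#: vector-bearing types used for planted sites, classic catalytic first
SITE_TYPES = ("HIS", "ASP", "GLU", "SER", "LYS", "ARG", "TYR", "CYS", "THR",
              "ASN", "GLN", "TRP")

#: decoys draw from all 20 standard types; the eight backbone-functional
#: ones contribute packing mass but no side-chain vector, as in real chains
DECOY_TYPES = STANDARD_AA

_MIN_CA_SEPARATION = 6.0  # Å, non-bonded Cα packing guard between residues
_MIN_TIP_CLEARANCE = 3.0  # Å, side-chain tip may not clash with another Cα


@dataclass(frozen=True)
class ToySiteSpec:
    """Parameters of one synthetic structure.

    ``displacement`` is the side-chain vector length in Å; negative values
    point the side chains away from the ring center (outward control).
    ``decoy_mode`` is ``"random"`` (uniform random directions) or
    ``"outward"`` (decoy side chains point away from the origin).
    ``decoy_shell`` defaults to a shell starting at the edge of the site
    sphere — ring radius plus the 10 Å surrounding-residue radius — so that
    decoys are genuinely outside the planted site rather than lining it.
    """

    n_site: int = 3
    ring_radius: float = 3.5
    displacement: float = 3.5
    n_decoys: int = 24
    decoy_mode: str = "random"
    seed: int = 0
    decoy_shell: tuple[float, float] | None = None
    jitter: float = 0.3

    def __post_init__(self) -> None:
        if self.ring_radius <= 0:
            raise GenerationError("ring radius must be positive")
        if self.n_site < 3:
            raise GenerationError("a planted site needs at least 3 residues")
        if self.decoy_mode not in ("random", "outward"):
            raise GenerationError(f"unknown decoy mode {self.decoy_mode!r}")

    @property
    def shell(self) -> tuple[float, float]:
        if self.decoy_shell is not None:
            return self.decoy_shell
        inner = self.ring_radius + 10.0
        return (inner, inner + 10.0)


def _format_atom(serial: int, name: str, resname: str, chain: str, resnum: int,
                 pos: np.ndarray) -> str:
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pad_name} {resname:3s} {chain:1s}{resnum:4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {name[0]:>2s}"
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_toy_structure(spec: ToySiteSpec) -> str:
    """Render the synthetic structure described by *spec* as PDB text.

    Deterministic for a fixed seed (byte-identical output).  Site residues
    occupy residue numbers 1..n_site of chain A; decoys follow.  Raises
    :class:`GenerationError` if decoys cannot be placed without clashes.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.zeros(3)

    residues: list[tuple[str, np.ndarray, np.ndarray]] = []  # (type, ca, vec atom)

    # planted site: Cα ring in the xy-plane around the origin
    for k in range(spec.n_site):
        ang = 2.0 * np.pi * k / spec.n_site
        ca = np.array([spec.ring_radius * np.cos(ang),
                       spec.ring_radius * np.sin(ang), 0.0])
        ca = ca + rng.normal(0.0, spec.jitter, 3)
        direction = _unit(center - ca)
        direction = _unit(direction + rng.normal(0.0, 0.1, 3))
        vec_atom = ca + spec.displacement * direction
        residues.append((SITE_TYPES[k % len(SITE_TYPES)], ca, vec_atom))

    # decoys: random positions in a shell outside the site
    r_lo, r_hi = spec.shell
    placed: list[np.ndarray] = [r[1] for r in residues]
    for _ in range(spec.n_decoys):
        for _attempt in range(200):
            direction = _unit(rng.normal(size=3))
            radius = rng.uniform(r_lo, r_hi)
            ca = radius * direction
            if all(np.linalg.norm(ca - p) >= _MIN_CA_SEPARATION for p in placed):
                break
        else:
            raise GenerationError("could not place decoy without clashes")
        placed.append(ca)
        aa = DECOY_TYPES[rng.integers(len(DECOY_TYPES))]
        residues.append((aa, ca, None))

    # decoy side chains: random (or radially outward) directions, rejecting
    # tips that would clash with another residue's Cα (side chains cannot
    # point into an occupied neighbor); backbone-functional types get none
    all_ca = [ca for _, ca, _ in residues]
    for k in range(spec.n_site, len(residues)):
        aa, ca, _ = residues[k]
        if aa not in SIDECHAIN_VECTOR_ATOMS:
            continue
        if spec.decoy_mode == "outward":
            tip = ca + abs(spec.displacement) * _unit(ca - center)
        else:
            tip = None
            for _attempt in range(200):
                cand = ca + abs(spec.displacement) * _unit(rng.normal(size=3))
                if all(np.linalg.norm(cand - other) >= _MIN_TIP_CLEARANCE
                       for i, other in enumerate(all_ca) if i != k):
                    tip = cand
                    break
            if tip is None:
                raise GenerationError("could not orient decoy side chain "
                                      "without atom overlap")
        residues[k] = (aa, ca, tip)

    lines = ["HEADER    SYNTHETIC FIXTURE"]
    serial = 1
    for resnum, (aa, ca, vec) in enumerate(residues, start=1):
        backbone = {
            "N": ca + np.array([-1.0, 0.45, 0.0]),
            "CA": ca,
            "C": ca + np.array([1.0, 0.45, 0.0]),
            "O": ca + np.array([1.2, 1.65, 0.0]),
        }
        for name, pos in backbone.items():
            lines.append(_format_atom(serial, name, aa, "A", resnum, pos))
            serial += 1
        if vec is not None:
            lines.append(_format_atom(serial, SIDECHAIN_VECTOR_ATOMS[aa], aa,
                                      "A", resnum, vec))
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
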