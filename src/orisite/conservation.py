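"""Sequence conservation from a PSI-Blast ASCII PSSM.

The per-position "information per position" column (bits) of an NCBI
PSI-Blast ASCII PSSM (``-out_ascii_pssm``) serves as a conservation score
c_j.  It is z-normalized over all positions of the chain (population
statistics) and fused with the structure score as

    S′_j = S_j + weight × z^c_j        (default weight 1.6)

Running PSI-Blast is out of scope; for reference, the profiles this package
was designed around come from three iterations against nr with an E-value
inclusion threshold of 5e-3.  The information column is identified
positionally (second-to-last numeric column) because NCBI header wording
varies across versions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, MappingError
from .structure_io import Structure

logger = logging.getLogger(__name__)

CONSERVATION_WEIGHT_DEFAULT = 1.6

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ConservationProfile:
    """Per-position conservation and (after mapping) per-residue z-scores."""

    positions: np.ndarray          # 1-based PSSM positions
    sequence: str                  # one-letter, in PSSM order
    c: np.ndarray                  # information per position, bits
    mean: float = 0.0
    sd: float = 0.0
    z: np.ndarray | None = None    # per PSSM position
    #: residue index (into Structure.residues) -> PSSM row index
    residue_to_position: dict[int, int] = field(default_factory=dict)
    unmapped: list[int] = field(default_factory=list)

    def z_for_residue(self, residue_index: int) -> float:
        row = self.residue_to_position.get(residue_index)
        if row is None or self.z is None:
            return 0.0
        return float(self.z[row])


def read_pssm(pssm_text: str) -> ConservationProfile:
    """Parse an NCBI PSI-Blast ASCII PSSM.

    Data rows are ``pos  aa  20 scores  20 percentages  info  weight``; the
    information-per-position value is taken as the second-to-last numeric
    column.  Raises :class:`FormatError` (with the line number) on malformed
    rows or an empty file.
    """
    positions: list[int] = []
    letters: list[str] = []
    info: list[float] = []
    for lineno, raw in enumerate(pssm_text.splitlines(), start=1):
        tokens = raw.split()
        if len(tokens) < 4:
            continue
        if not (tokens[0].lstrip("-").isdigit() and tokens[1] in _AA_LETTERS):
            continue  # header / trailer lines
        try:
            pos = int(tokens[0])
            values = [float(t) for t in tokens[2:]]
        except ValueError as exc:
            raise FormatError(f"PSSM line {lineno}: non-numeric field: {exc}") from exc
        if len(values) < 42:  # 20 + 20 + info + weight
            raise FormatError(
                f"PSSM line {lineno}: expected 42 numeric columns, got {len(values)}"
            )
        positions.append(pos)
        letters.append(tokens[1])
        info.append(values[-2])
    if not positions:
        raise FormatError("no PSSM data rows found")
    if positions != list(range(1, len(positions) + 1)):
        raise FormatError("PSSM positions are not contiguous starting at 1")
    return ConservationProfile(
        positions=np.asarray(positions),
        sequence="".join(letters),
        c=np.asarray(info, dtype=float),
    )


def map_to_structure(
    profile: ConservationProfile,
    structure: Structure,
    chain: str,
) -> ConservationProfile:
    """Map PSSM positions onto the residues of one chain and normalize.

    The chain's one-letter sequence must match the PSSM sequence exactly, or
    occur as a contiguous substring of it (missing leading/trailing residues
    in the structure), or contain the PSSM sequence as a substring (extra
    structure residues become unmapped, z^c = 0, with a warning).  Anything
    else raises :class:`MappingError`.  z^c uses population statistics over
    ALL PSSM positions of the chain.
    """
    chain_res = [
        (idx, r) for idx, r in enumerate(structure.residues) if r.chain_id == chain
    ]
    if not chain_res:
        raise MappingError(f"structure has no residues in chain {chain!r}")
    struct_seq = structure.chain_sequence(chain)
    pssm_seq = profile.sequence

    mapping: dict[int, int] = {}
    unmapped: list[int] = []
    if struct_seq == pssm_seq or struct_seq in pssm_seq:
        offset = pssm_seq.index(struct_seq)
        for k, (idx, _) in enumerate(chain_res):
            mapping[idx] = offset + k
    elif pssm_seq in struct_seq:
        offset = struct_seq.index(pssm_seq)
        for k, (idx, _) in enumerate(chain_res):
            row = k - offset
            if 0 <= row < len(pssm_seq):
                mapping[idx] = row
            else:
                unmapped.append(idx)
        warnings.warn(
            f"{len(unmapped)} residues of chain {chain} not covered by the "
            "PSSM; their conservation z-score is 0", stacklevel=2,
        )
    else:
        raise MappingError(
            f"PSSM sequence does not match chain {chain} (no exact or "
            "offset alignment); supply a PSSM computed for this chain"
        )

    mean = float(profile.c.mean())
    sd = float(profile.c.std())  # population SD
    if sd == 0.0:
        warnings.warn("constant conservation profile; z^c set to 0", stacklevel=2)
        z = np.zeros_like(profile.c)
    else:
        z = (profile.c - mean) / sd
    return ConservationProfile(
        positions=profile.positions,
        sequence=profile.sequence,
        c=profile.c,
        mean=mean,
        sd=sd,
        z=z,
        residue_to_position=mapping,
        unmapped=unmapped,
    )


def fuse_scores(scores, profile: ConservationProfile | None,
                weight: float = CONSERVATION_WEIGHT_DEFAULT) -> None:
    """Write S′ = S + weight·z^c onto each :class:`ResidueScore` in place.

    Residues without a mapped PSSM position (or when *profile* is ``None``)
    use z^c = 0, so with weight 0 or an absent profile the fused ranking
    equals the structure-only ranking.
    """
    for rs in scores:
        zc = profile.z_for_residue(rs.residue_index) if profile is not None else 0.0
        rs.z_c = zc
        rs.S_prime = rs.S + weight * zc
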