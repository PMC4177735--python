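"""Read PDB structures into a lightweight residue/atom model.

The downstream geometry only needs, for every residue, the Cα position and
(for the twelve amino-acid types whose functional atom sits on the side
chain) one designated *side-chain vector atom*.  This module parses a PDB
file with :mod:`gemmi`, resolves alternate locations, strips non-protein
content and exposes that reduced model.

The side-chain vector atom per type is the atom closest to the residue's
usual functional group:

====  ====
ARG   CZ
ASN   CG
ASP   CG
CYS   SG
GLN   CD
GLU   CD
HIS   NE2
LYS   NZ
SER   OG
THR   OG1
TRP   CZ2
TYR   OH
====  ====

The remaining eight types (ALA, GLY, ILE, LEU, MET, PHE, PRO, VAL) have no
vector atom: their functional atom, when catalytic, is usually on the
backbone, and they are excluded from orientation scoring (they still count
for contact-number flexibility and appear in the auxiliary backbone report).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import EmptyStructureError, FormatError, InvalidResidueTypeError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by three-letter code.
STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Designated side-chain vector atom per amino-acid type (PDB nomenclature).
SIDECHAIN_VECTOR_ATOMS = {
    "ARG": "CZ", "ASN": "CG", "ASP": "CG", "CYS": "SG",
    "GLN": "CD", "GLU": "CD", "HIS": "NE2", "LYS": "NZ",
    "SER": "OG", "THR": "OG1", "TRP": "CZ2", "TYR": "OH",
}

#: Nonstandard residue names mapped onto a standard parent type.
NONSTANDARD_PARENT = {"MSE": "MET"}


def sidechain_vector_atom(aa_type: str) -> str | None:
    """Return the side-chain vector atom name for *aa_type*, or ``None``.

    ``None`` means the type has no side-chain vector atom (backbone-functional
    types).  Unknown codes raise :class:`InvalidResidueTypeError`.
    """
    aa = aa_type.upper()
    if aa not in AA_INDEX:
        raise InvalidResidueTypeError(f"unknown amino-acid type {aa_type!r}")
    return SIDECHAIN_VECTOR_ATOMS.get(aa)


@dataclass(frozen=True)
class Atom:
    """A single atom: PDB name, Cartesian position in Å, occupancy, altloc."""

    name: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise FormatError(f"atom {self.name!r}: non-finite or malformed position")
        object.__setattr__(self, "position", pos)


@dataclass
class Residue:
    """One residue: identity, type and its atoms (one per name after altloc
    resolution)."""

    chain_id: str
    seq_num: int
    icode: str
    aa: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    #: True when the residue is a HETATM record mapped onto a standard parent
    #: (e.g. selenomethionine); such residues keep their Cα but never get a
    #: side-chain vector.
    from_nonstandard: bool = False

    @property
    def identity(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.aa}{self.seq_num}{self.icode}".rstrip()

    @property
    def ca(self) -> np.ndarray | None:
        atom = self.atoms.get("CA")
        return None if atom is None else atom.position

    @property
    def has_sidechain_vector(self) -> bool:
        if self.from_nonstandard:
            return False
        name = SIDECHAIN_VECTOR_ATOMS.get(self.aa)
        return name is not None and name in self.atoms

    @property
    def vector_atom_position(self) -> np.ndarray | None:
        if not self.has_sidechain_vector:
            return None
        return self.atoms[SIDECHAIN_VECTOR_ATOMS[self.aa]].position


@dataclass
class Structure:
    """An ordered list of residues from the first model of a PDB file."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    model_index: int = 1
    #: residues that looked like amino acids but lacked a Cα and were dropped
    n_dropped_no_ca: int = 0

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coordinates(self) -> np.ndarray:
        """(n, 3) array of Cα positions, in residue order."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain, in file order."""
        return "".join(
            THREE_TO_ONE[r.aa] for r in self.residues if r.chain_id == chain_id
        )


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties prefer altloc 'A', then first seen."""
    if len(atoms) == 1:
        return atoms[0]
    best = max(a.occ for a in atoms)
    tied = [a for a in atoms if a.occ == best]
    for a in tied:
        if a.altloc == "A":
            return a
    return tied[0]


def read_structure(
    pdb_text: str,
    chain_filter: set[str] | None = None,
    structure_id: str = "",
) -> Structure:
    """Parse PDB text into a :class:`Structure` (first model only).

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: altloc ``A``, then first seen).  Residues lacking a Cα atom are
    dropped; amino-acid-named ones among them are counted in
    ``n_dropped_no_ca``.  Raises :class:`FormatError` on unparsable input and
    :class:`EmptyStructureError` when nothing usable remains.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB input: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError("PDB input contains no model")

    model = st[0]
    out = Structure(id=structure_id or st.name.strip() or "structure")
    amino_names = set(STANDARD_AA) | set(NONSTANDARD_PARENT)
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms: dict[str, Atom] = {}
            for name, alts in by_name.items():
                a = _pick_altloc(alts)
                atoms[name] = Atom(
                    name=name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    altloc=a.altloc if a.altloc not in ("\0", "\x00") else "",
                )
            if "CA" not in atoms:
                if res.name in amino_names:
                    out.n_dropped_no_ca += 1
                    logger.warning(
                        "residue %s %s%d%s has no CA atom; dropped",
                        res.name, chain.name, res.seqid.num, res.seqid.icode.strip(),
                    )
                continue
            out.residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_num=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    aa=res.name,
                    atoms=atoms,
                    from_nonstandard=res.name in NONSTANDARD_PARENT,
                )
            )
    if not out.residues:
        raise EmptyStructureError("no residue with a CA atom in the selected chains")
    return out


def strip_nonprotein(structure: Structure) -> Structure:
    """Remove everything that is not a standard protein residue.

    Waters, ions and ligands disappear; MSE is kept as MET (Cα usable, no
    side-chain vector); any other nonstandard residue is removed.  Returns a
    new :class:`Structure`; the input is not modified.
    """
    kept: list[Residue] = []
    for res in structure.residues:
        if res.aa in AA_INDEX:
            kept.append(res)
        elif res.aa in NONSTANDARD_PARENT:
            kept.append(
                Residue(
                    chain_id=res.chain_id,
                    seq_num=res.seq_num,
                    icode=res.icode,
                    aa=NONSTANDARD_PARENT[res.aa],
                    atoms=res.atoms,
                    from_nonstandard=True,
                )
            )
        else:
            logger.debug("stripping non-protein residue %s", res.label)
    return Structure(
        id=structure.id,
        residues=kept,
        model_index=structure.model_index,
        n_dropped_no_ca=structure.n_dropped_no_ca,
    )


def read_annotations(tsv_path_or_buffer) -> "pd.DataFrame":
    """Read a catalytic-site annotation table.

    Tab-separated, ``#`` comments, columns
    ``structure_id  chain  resnum  icode  site_id`` and optionally ``aa``
    (3-letter type, required for profile building).
    """
    import pandas as pd

    names = ["structure_id", "chain", "resnum", "icode", "site_id", "aa"]
    df = pd.read_csv(
        tsv_path_or_buffer,
        sep="\t",
        comment="#",
        header=None,
        names=names,
        dtype=str,
        skip_blank_lines=True,
    )
    if df["site_id"].isna().any():
        raise FormatError("annotation TSV needs at least 5 columns "
                          "(structure_id chain resnum icode site_id [aa])")
    df["resnum"] = df["resnum"].astype(int)
    df["icode"] = df["icode"].fillna("").replace("-", "")
    if df["aa"].notna().any():
        df["aa"] = df["aa"].str.upper()
    return df
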