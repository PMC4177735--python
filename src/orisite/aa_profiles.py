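"""Amino-acid combination profiles from catalytic-site annotations.

Catalytic sites show strong amino-acid co-occurrence preferences (His with
Asp, Ser with His, ...).  From a table of annotated sites we build, for each
amino-acid type x, a 20-element frequency profile p_x whose entry p_x^y is
the frequency with which type y occurs in the same catalytic site as type x.
A residue triplet (j; y, z) is then scored from residue j's row as
a_j = p_x^y + p_x^z, and a_j is z-normalized per protein over the multiset
of all triplet-membership scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyProfileError, FormatError, InvalidResidueTypeError
from .structure_io import AA_INDEX, STANDARD_AA


@dataclass
class ProfileSet:
    """20x20 co-occurrence frequency matrix; row x is the profile p_x.

    Rows with any observation sum to 1; types never seen in a site keep an
    all-zero row.  The matrix is generally not symmetric after row
    normalization.
    """

    p: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (20, 20):
            raise FormatError(f"profile matrix must be 20x20, got {self.p.shape}")
        if np.any(self.p < 0):
            raise FormatError("profile frequencies must be non-negative")

    def value(self, x: str, y: str) -> float:
        """p_x^y: frequency of type y co-occurring with type x."""
        return float(self.p[_aa_index(x), _aa_index(y)])

    def row(self, x: str) -> np.ndarray:
        return self.p[_aa_index(x)]

    def to_tsv(self, path_or_buffer) -> None:
        df = pd.DataFrame(self.p, index=STANDARD_AA, columns=STANDARD_AA)
        df.to_csv(path_or_buffer, sep="\t", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path_or_buffer, provenance: str = "") -> "ProfileSet":
        df = pd.read_csv(path_or_buffer, sep="\t", index_col=0)
        if list(df.index) != list(STANDARD_AA) or list(df.columns) != list(STANDARD_AA):
            raise FormatError("profile TSV must have the 20 standard 3-letter "
                              "codes as row and column headers, alphabetical")
        return cls(p=df.to_numpy(dtype=float), provenance=provenance)


@dataclass
class CombinationScore:
    """z-normalized combination scores with the population statistics used."""

    a: np.ndarray
    z: np.ndarray
    mean: float
    sd: float
    degenerate: bool = field(default=False)


def _aa_index(aa: str) -> int:
    try:
        return AA_INDEX[aa.upper()]
    except KeyError:
        raise InvalidResidueTypeError(f"unknown amino-acid type {aa!r}") from None


def build_profiles(sites: Iterable[Sequence[str]], provenance: str = "") -> ProfileSet:
    """Build a :class:`ProfileSet` from catalytic sites.

    *sites* is an iterable of sites, each a sequence of 3-letter residue
    types (one entry per residue instance).  Within a site every unordered
    pair of distinct residue instances contributes one co-occurrence count in
    both directions; a residue never pairs with itself.  Counts are
    row-normalized to frequencies.  Raises :class:`EmptyProfileError` when no
    site has at least two residues.
    """
    counts = np.zeros((20, 20), dtype=float)
    any_pair = False
    for site in sites:
        idx = [_aa_index(aa) for aa in site]
        if len(idx) < 2:
            continue
        any_pair = True
        for i in range(len(idx)):
            for j in range(len(idx)):
                if i != j:
                    counts[idx[i], idx[j]] += 1.0
    if not any_pair:
        raise EmptyProfileError("no catalytic site with >= 2 residues")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row_sums > 0, counts / row_sums, 0.0)
    return ProfileSet(p=p, provenance=provenance)


def profiles_from_annotations(annotations: pd.DataFrame, provenance: str = "") -> ProfileSet:
    """Build profiles from an annotation table (see
    :func:`orisite.structure_io.read_annotations`); requires the ``aa``
    column, groups residues by (structure_id, site_id)."""
    if "aa" not in annotations or annotations["aa"].isna().any():
        raise FormatError("profile building needs the 'aa' column in the "
                          "annotation TSV")
    sites = [
        list(group["aa"])
        for _, group in annotations.groupby(["structure_id", "site_id"], sort=True)
    ]
    return build_profiles(sites, provenance=provenance)


def combination_score(x: str, y: str, z: str, profiles: ProfileSet) -> float:
    """a = p_x^y + p_x^z, scored asymmetrically from residue j's (type x) row."""
    return profiles.value(x, y) + profiles.value(x, z)


def normalize_combination(a_values: np.ndarray) -> CombinationScore:
    """z-normalize a protein's multiset of combination scores.

    Population statistics over every triplet-membership a value evaluated
    for the protein.  A zero-spread multiset yields all-zero z-scores with a
    warning (degenerate case).
    """
    a = np.asarray(a_values, dtype=float)
    mean = float(a.mean())
    sd = float(a.std())
    if sd == 0.0:
        warnings.warn("constant combination scores; z set to 0", stacklevel=2)
        return CombinationScore(a=a, z=np.zeros_like(a), mean=mean, sd=0.0,
                                degenerate=True)
    return CombinationScore(a=a, z=(a - mean) / sd, mean=mean, sd=sd)


def default_profiles() -> ProfileSet:
    """The bundled default :class:`ProfileSet`.

    Built (and rebuildable bit-identically via
    :func:`profiles_from_annotations`) from the SYNTHETIC catalytic-site
    composition table shipped with the package — a hand-curated list of
    classic catalytic-site compositions, not a published survey; supply your
    own annotation TSV for production use.
    """
    from importlib.resources import files

    text = files("orisite.data").joinpath("default_profile.synthetic.tsv").read_text()
    return ProfileSet.from_tsv(StringIO(text), provenance="bundled synthetic default")


def default_site_annotations() -> pd.DataFrame:
    """The SYNTHETIC annotation table the default profile is built from."""
    from importlib.resources import files

    from .structure_io import read_annotations

    text = files("orisite.data").joinpath("site_annotations.synthetic.tsv").read_text()
    return read_annotations(StringIO(text))
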