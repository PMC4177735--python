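"""Exception hierarchy shared by all orisite modules."""


class OrisiteError(Exception):
    """Base class for all errors raised by orisite."""


class FormatError(OrisiteError):
    """Input file could not be parsed (PDB, PSSM, TSV)."""


class EmptyStructureError(OrisiteError):
    """No usable protein residue survived reading/filtering."""


class DegenerateStructureError(OrisiteError):
    """Geometry too degenerate to proceed (e.g. all Cα coincident)."""


class CoincidentAtomError(OrisiteError):
    """Two residues share identical Cα coordinates (zero distance)."""


class NormalizationError(OrisiteError):
    """A z-score normalization is undefined (zero spread)."""


class InvalidResidueTypeError(OrisiteError):
    """Unknown amino-acid three-letter code."""


class UndefinedAngleError(OrisiteError):
    """Angle requested for a point coincident with the residue Cα."""


class EmptyProfileError(OrisiteError):
    """No multi-residue catalytic site available to build profiles."""


class MappingError(OrisiteError):
    """PSSM sequence could not be mapped onto the structure chain."""


class UndefinedCurveError(OrisiteError):
    """ROC / recall-precision curve undefined for single-class labels."""


class GenerationError(OrisiteError):
    """Synthetic-structure generation hit infeasible geometry."""


class SizeLimitError(OrisiteError):
    """Input structure exceeds the residue-count guard."""
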