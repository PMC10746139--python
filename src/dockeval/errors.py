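"""Exception hierarchy for dockeval."""


class DockevalError(Exception):
    """Base class for all dockeval errors."""


class StructureParseError(DockevalError):
    """A structure file could not be parsed."""


class EmptyStructureError(DockevalError):
    """A structure file contained no coordinate records."""


class UnknownLigandError(DockevalError):
    """The requested ligand id is not present in the structure."""


class AmbiguousLigandError(DockevalError):
    """The requested ligand id matches hetero groups in more than one chain."""


class MappingError(DockevalError):
    """Residue correspondence between two structures could not be established."""


class SuperpositionError(DockevalError):
    """A rigid superposition is underdetermined or its atom sets do not match."""


class InsufficientOverlapError(SuperpositionError):
    """Fewer than the minimum number of shared atoms/residues are available."""


class CorrespondenceError(DockevalError):
    """Two ligand poses cannot be placed in atom-to-atom correspondence."""


class SmilesParseError(DockevalError):
    """A SMILES string is invalid or describes a multi-fragment species."""


class SizeLimitError(DockevalError):
    """A molecule exceeds the size cap of the exact MCS search."""


class InsufficientDataError(DockevalError):
    """A statistical routine received too few records or pairs."""


class GenerationError(DockevalError):
    """The synthetic-data generator could not realize a requested target."""
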