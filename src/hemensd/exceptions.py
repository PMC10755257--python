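"""Exception hierarchy."""


class HemensdError(Exception):
    """Base class for all package errors."""


class ConstructiveGeometryError(HemensdError):
    """The requested bond parameters cannot close the macrocycle."""


class IncompleteSkeletonError(HemensdError):
    """A required porphyrin-skeleton atom is missing."""


class GeometryError(HemensdError):
    """Degenerate geometry (coincident or collinear atoms)."""


class ForceFieldError(HemensdError):
    """Non-finite energy or invalid force-field evaluation."""


class ModeIdentificationError(HemensdError):
    """A required normal mode could not be identified by symmetry."""


class BasisFormatError(HemensdError):
    """A mode-basis file is malformed or fails validation."""


class StructureParseError(HemensdError):
    """An mmCIF file could not be parsed or lacks an atom table."""


class DimensionError(HemensdError):
    """Vector/matrix dimensions do not match the 25-atom convention."""
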