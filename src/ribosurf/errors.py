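"""Exception hierarchy.

Every error raised by the library derives from :class:`RibosurfError` so the
CLI can translate any failure into a single-line reason and a nonzero exit.
"""


class RibosurfError(Exception):
    """Base class for all ribosurf errors."""


class FormatError(RibosurfError):
    """File is not in a recognized/declared structure format."""


class EmptyStructureError(RibosurfError):
    """Structure contains no polymer chains after filtering."""


class CoordinateRangeError(RibosurfError):
    """Coordinate does not fit the fixed-column PDB field."""


class ConfigurationError(RibosurfError):
    """Invalid or inconsistent run configuration."""


class ScoringError(RibosurfError):
    """A chain cannot be scored (no representative atoms / zero SASA)."""


class DegenerateSeparationError(RibosurfError):
    """Auto-thresholding failed because all radial scores coincide."""


class RadiusLookupError(RibosurfError):
    """No van der Waals radius for an element."""


class TableError(RibosurfError):
    """Malformed or inconsistent nomenclature table."""


class ConsistencyError(RibosurfError):
    """Cross-module inputs refer to different structures."""


class InputError(RibosurfError):
    """Invalid user-facing input (gene lists, count matrices, fixture specs)."""
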