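"""Exception hierarchy for corescan.

All package errors derive from :class:`CoreScanError` so callers can catch a
single base class at CLI boundaries.
"""


class CoreScanError(Exception):
    """Base class for all corescan errors."""


class FormatError(CoreScanError):
    """A file does not parse in its declared dialect (or is empty)."""


class CharacterError(FormatError):
    """An illegal character in a sequence; message names the offending position."""


class RecordError(CoreScanError):
    """A single record is malformed (e.g. start > end in an annotation)."""


class UnknownGeneError(CoreScanError, KeyError):
    """A requested gene identifier is not present in the annotation set."""


class ContractError(CoreScanError, ValueError):
    """A caller violated an operation precondition (e.g. length mismatch)."""


class AlignmentError(CoreScanError):
    """An alignment violates a structural requirement (e.g. gap in the element span)."""


class ConfigurationError(CoreScanError):
    """Inconsistent or infeasible configuration."""


class DomainCoordinatesError(ConfigurationError):
    """Required sigma-domain coordinates are missing in strict mode."""
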