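"""Exception hierarchy for the CAD pipeline.

Each stage raises a narrow subclass of :class:`PancradError` so callers can
distinguish malformed inputs from genuine processing failures.
"""


class PancradError(Exception):
    """Base class for all package errors."""


class InputFormatError(PancradError):
    """File could not be parsed as NIfTI or a DICOM series."""


class MetadataError(PancradError):
    """Required physical metadata (spacing, orientation) is missing."""


class CoRegistrationError(PancradError):
    """Volume and mask do not share a physical frame."""


class EmptyROIError(PancradError):
    """An operation requiring a non-empty region received an empty one."""


class DegenerateROIError(PancradError):
    """ROI too small for the requested texture computation."""


class FilterSupportError(PancradError):
    """Image smaller than the filter kernel support."""


class ConfigurationError(PancradError):
    """Unknown feature id, bad manifest entry or invalid spec parameter."""


class SchemaError(PancradError):
    """Feature names/order at predict time do not match fit time."""


class TrainingError(PancradError):
    """Training preconditions violated (single-class split, NaNs, ...)."""


class StateError(PancradError):
    """Operation invoked before its prerequisites (e.g. unscored patches)."""


class IncompleteStudyError(PancradError):
    """A study is missing one of the scores needed for a decision."""
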