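"""Exception hierarchy shared across the pipeline stages."""


class VitalkinError(Exception):
    """Base class for all package errors."""


class FormatError(VitalkinError):
    """Malformed or inconsistent trial file (bad rows, non-uniform time base)."""


class DataError(VitalkinError):
    """Recording content violates a data contract (gaps, missing markers)."""


class GeometryError(VitalkinError):
    """Impossible body geometry (unreachable wrist, coincident centroids)."""


class SegmentationError(VitalkinError):
    """Movement phases could not be identified (e.g. no movement detected)."""


class DegenerateInputError(VitalkinError):
    """Input has no usable spread (constant signal, zero-length chord)."""


class ConfigurationError(VitalkinError):
    """Invalid or incomplete pipeline/generator configuration."""
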