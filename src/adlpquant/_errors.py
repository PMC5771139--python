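"""Exception hierarchy shared across the pipeline."""


class AdlpQuantError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AdlpQuantError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(AdlpQuantError, ValueError):
    """Parsed data violates an invariant of its domain type."""
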