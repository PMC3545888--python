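"""Exception hierarchy shared across the package."""


class BaculokitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BaculokitError):
    """A file does not conform to the expected format."""


class IntegrityError(BaculokitError):
    """Internally inconsistent data (coordinates, pairings, spans)."""


class ParameterError(BaculokitError):
    """An operation was called with an out-of-range parameter."""


class FitError(BaculokitError):
    """A model fit could not be performed on the given data."""


class GenerationError(BaculokitError):
    """The synthetic-data generator could not satisfy its constraints."""
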