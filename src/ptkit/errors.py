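"""Exception hierarchy shared by all ptkit modules."""


class PtkitError(Exception):
    """Base class for all ptkit errors."""


class FormatError(PtkitError):
    """A file does not have the expected layout (missing columns, bad header)."""


class IntegrityError(PtkitError):
    """A stream violates its sampling contract (gaps, duplicates, long NaN runs)."""


class ValidationError(PtkitError):
    """Domain-level data is inconsistent (overlapping events, negative counts)."""


class ParameterError(PtkitError, ValueError):
    """An algorithm parameter is out of its admissible range."""


class InsufficientDataError(PtkitError):
    """Not enough samples or events to compute the requested quantity."""
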