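"""Exception hierarchy for the ewhk package."""


class EwhkError(Exception):
    """Base class for all package errors."""


class FormatError(EwhkError, ValueError):
    """A file does not conform to the spectra CSV dialect."""


class ValidationError(EwhkError, ValueError):
    """Input data violates a documented precondition or invariant."""


class DegenerateSampleError(ValidationError):
    """A sample is degenerate for the requested operation (e.g. flat
    spectrum segment, for which SNV is undefined)."""


class NotFittedError(EwhkError, RuntimeError):
    """A model method requiring a fitted model was called before fit."""
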