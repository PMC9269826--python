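"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class FormatError(ValidationError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class DegenerateSignalError(ValueError):
    """A signal is too short, all-zero, or otherwise unusable for the operation."""


class NoPeakError(RuntimeError):
    """No spectral or time-domain peak could be found; callers fall back."""


class NoCandidateError(RuntimeError):
    """No vital-sign candidate survived screening for a window."""


class ConfigurationError(ValueError):
    """A configuration combination is invalid or outside the model's valid range."""
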