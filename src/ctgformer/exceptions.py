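"""Exception types shared across the package."""


class CTGError(Exception):
    """Base class for all package errors."""


class ParameterError(CTGError, ValueError):
    """An argument or configuration value violates its contract."""


class ValidationError(CTGError, ValueError):
    """Input data fails a structural precondition (empty trace, bad range)."""


class DegenerateChannelError(CTGError):
    """A channel has no observed samples, so per-sequence statistics are undefined."""


class DegenerateWindowError(CTGError):
    """A window has no valid patch on some channel; pooling is undefined."""


class AUCUndefinedError(CTGError):
    """ROC/AUC requested on a prediction set with a single class."""


class UnreachableTargetError(CTGError):
    """No threshold attains the requested sensitivity/specificity floor."""


class SplitError(CTGError, ValueError):
    """Cohort too small (or malformed) to split."""
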