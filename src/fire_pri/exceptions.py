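"""Exception hierarchy shared across the package."""


class FirePriError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FirePriError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(FirePriError, ValueError):
    """Input violates a documented invariant or precondition."""


class CapacityError(ValidationError):
    """More items were requested than the candidate universe contains."""


class UndefinedMetricError(FirePriError, ArithmeticError):
    """A metric or ratio is undefined for the given counts."""
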