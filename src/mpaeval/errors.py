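"""Exception hierarchy shared across the package."""


class MpaEvalError(Exception):
    """Base class for all package errors."""


class FormatError(MpaEvalError):
    """An input file does not follow the expected tabular contract."""


class ValidationError(MpaEvalError):
    """A record violates a field-level invariant (bad value, bad row)."""


class DesignError(MpaEvalError):
    """The sampling design cannot support the requested model fit."""
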