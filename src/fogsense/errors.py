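"""Exception hierarchy shared across the package.

Validation problems (bad files, bad configs, bad annotations) derive from
:class:`ValidationError`; they map to CLI exit code 2.  Everything else that
the package raises deliberately derives from :class:`FogSenseError` and maps
to exit code 3.
"""


class FogSenseError(Exception):
    """Base class for all errors raised by fogsense."""


class ValidationError(FogSenseError, ValueError):
    """Invalid user-supplied input (file, config, annotation, parameter)."""


class SchemaError(ValidationError):
    """A trace file's header does not map onto (side, muscle, channel)."""


class FormatError(ValidationError):
    """A file is structurally broken: NaN cells, non-monotone time, ..."""


class DegenerateInputError(FogSenseError):
    """An operation is undefined on this input (e.g. normalizing zeros)."""


class ContractViolation(FogSenseError):
    """Caller broke an operation's precondition (grid/side mismatch, ...)."""


class TooShortError(FogSenseError):
    """The analysed interval is too short for a reliable estimate."""
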