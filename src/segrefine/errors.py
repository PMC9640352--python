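"""Exception taxonomy shared by the library and the CLI.

Exit-code mapping used by the command line front end: usage errors exit 2,
input/format errors exit 3, computation errors exit 4.
"""


class SegRefineError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(SegRefineError):
    """Caller violated an API contract (bad arguments, shape mismatch)."""

    exit_code = 2


class InputError(SegRefineError):
    """A required input is missing or unreadable."""

    exit_code = 3


class FormatError(SegRefineError):
    """An input file exists but does not satisfy the format contract."""

    exit_code = 3


class ComputationError(SegRefineError):
    """A numerical procedure failed (non-finite values, empty reduction)."""

    exit_code = 4
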