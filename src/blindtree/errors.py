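"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors exit 2, format errors 3,
spec/mapping errors 4.
"""


class BlindtreeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(BlindtreeError, ValueError):
    """A numeric argument violates a precondition (negative count, gamma outside (0,1), ...)."""


class WrongTestError(BlindtreeError, ValueError):
    """The count shape does not match the requested test.

    Raised e.g. when the multi-directional test is handed a count whose third
    slot is unobservable; the message names the test to use instead.
    """


class UndefinedTestError(BlindtreeError, ValueError):
    """The test is undefined for this input (e.g. symmetry test on (0, 0))."""


class FormatError(BlindtreeError, ValueError):
    """A file or count string could not be parsed."""


class MappingError(BlindtreeError, ValueError):
    """Taxa in one input are missing from another (matrix vs tree vs spec)."""


class SpecError(BlindtreeError, ValueError):
    """A node/trifurcation specification is inconsistent or unrealizable."""
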