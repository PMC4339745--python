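"""Exception hierarchy.

User errors (bad identifiers, unreadable files) and data errors (no
interface, degenerate geometry) are distinguished so the CLI can map them
to distinct exit codes.
"""


class PCalignError(Exception):
    """Base class for all package errors."""


class UserError(PCalignError):
    """Bad input from the caller: missing chains, unreadable paths, bad flags."""


class DataError(PCalignError):
    """The input was understood but does not support the computation."""


class ParseError(UserError):
    pass


class EmptyStructureError(DataError):
    pass


class MissingModelError(UserError):
    pass


class MissingChainError(UserError):
    pass


class MissingAtomsError(DataError):
    pass


class ClassificationError(UserError):
    pass


class LookupTableError(UserError):
    pass


class InsufficientDataError(DataError):
    pass


class NoInterfaceError(DataError):
    pass


class DegenerateGeometryError(DataError):
    pass


class MissingBackgroundError(UserError):
    pass


class ShapeError(UserError):
    pass


class GenerationError(UserError):
    pass
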