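"""Exception hierarchy shared across pipeline stages.

``InputError`` covers anything wrong with user-supplied files or arguments
(schema, parse, validation); ``StageError`` covers a failure inside a
pipeline stage after inputs were accepted.  The command-line layer maps
these onto exit codes 2 and 3 respectively.
"""


class NeoepiError(Exception):
    """Base class for all package errors."""


class InputError(NeoepiError):
    """Malformed or invalid input data (file schema, parse, validation)."""


class SchemaError(InputError):
    """A required column or field is missing from an input table."""


class ParseError(InputError):
    """A value or line could not be parsed."""


class ValidationError(InputError):
    """A parsed record violates an invariant (e.g. residue mismatch)."""


class StageError(NeoepiError):
    """A pipeline stage failed after its inputs were accepted."""
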