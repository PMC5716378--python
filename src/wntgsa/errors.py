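"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (input error -> 2,
degenerate data -> 3, pipeline failure -> 4).
"""


class WntGsaError(Exception):
    """Base class for all package errors."""


class InputError(WntGsaError, ValueError):
    """Malformed arguments: wrong shapes, unknown method tags, bad config."""


class DomainError(WntGsaError, ValueError):
    """Mathematically invalid values: points outside the unit cube,
    non-positive stimulus magnitudes, negative importance coefficients."""


class DegenerateDataError(WntGsaError, ValueError):
    """Data that carries no usable signal: constant columns, zero output
    variance, zero-range genes under min-max scaling."""


class PipelineError(WntGsaError, RuntimeError):
    """An experiment failed as a whole (e.g. most replicates errored)."""


class ParseError(InputError):
    """CSV parse failure; carries file/row/column context in the message."""

    def __init__(self, message: str, path=None, row=None, column=None):
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if row is not None:
            ctx.append(f"row={row}")
        if column is not None:
            ctx.append(f"column={column}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.path = path
        self.row = row
        self.column = column
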