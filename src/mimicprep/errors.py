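"""Exception hierarchy shared by all mimicprep modules.

Every error raised on purpose by the package derives from
:class:`MimicPrepError`, so callers (and the CLI) can distinguish expected
failure modes from bugs.  The CLI maps the subclasses to exit codes:
usage errors -> 2, parse errors -> 3, chemistry errors -> 4.
"""

from __future__ import annotations


class MimicPrepError(Exception):
    """Base class for all errors raised by mimicprep."""


class UsageError(MimicPrepError):
    """Invalid arguments, missing inputs, or violated preconditions."""


class ParseError(MimicPrepError):
    """A text input could not be parsed.

    Parameters
    ----------
    message:
        Human-readable description of the problem.
    path:
        File being parsed, if any.
    line:
        1-based line number where the problem was found.
    column:
        0-based character position (used by the selection parser).
    """

    def __init__(self, message: str, path=None, line: int | None = None,
                 column: int | None = None):
        self.path = path
        self.line = line
        self.column = column
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"position {column}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class ChemistryError(MimicPrepError):
    """Chemically inconsistent request: unresolved elements, open valences,
    missing pseudopotential entries."""


class NonIntegralChargeWarning(UserWarning):
    """The QM region's summed partial charge is not close to an integer,
    which usually means the selection severed a charge group."""
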