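"""Exception hierarchy shared across the package."""

from __future__ import annotations


class GuildAssemblyError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GuildAssemblyError, ValueError):
    """Invalid parameter or inconsistent in-memory data structure."""


class ParseError(GuildAssemblyError, ValueError):
    """A file could not be parsed; carries file/line/column context."""

    def __init__(self, message: str, *, path=None, line: int | None = None,
                 column: int | None = None):
        loc = []
        if path is not None:
            loc.append(f"file={path}")
        if line is not None:
            loc.append(f"line={line}")
        if column is not None:
            loc.append(f"column={column}")
        full = message if not loc else f"{message} [{', '.join(loc)}]"
        super().__init__(full)
        self.path = path
        self.line = line
        self.column = column


class ConfigError(GuildAssemblyError, ValueError):
    """Run configuration is missing keys or contains unknown ones."""


class DegenerateStatisticError(GuildAssemblyError, ValueError):
    """A statistic is undefined on the given input (zero variance etc.)."""
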