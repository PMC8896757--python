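"""Exception types shared across the package."""


class ThermoenvError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ThermoenvError):
    """A file did not conform to its declared dialect.

    Readers never silently repair malformed input; the message names the
    offending file and, where known, the 1-based line number.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = str(path) if path is not None else None
        self.line = line
        prefix = ""
        if self.path is not None:
            prefix = self.path
            if line is not None:
                prefix += f":{line}"
            prefix += ": "
        super().__init__(prefix + message)


class InvariantError(ThermoenvError, ValueError):
    """A domain-type invariant was violated."""
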