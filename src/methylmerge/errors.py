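"""Exception hierarchy shared across the package."""


class MethylmergeError(Exception):
    """Base class for all package errors."""


class CallFormatError(MethylmergeError):
    """A call file line or header could not be parsed.

    Carries the offending path and 1-based line number when known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class DataIntegrityError(MethylmergeError):
    """Counts or coordinates violate an invariant (e.g. depth < n_meth)."""


class UsageError(MethylmergeError):
    """Invalid arguments to an operation (e.g. zero call sets to integrate)."""
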