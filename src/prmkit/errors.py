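"""Exception types shared across the package."""


class PrmkitError(Exception):
    """Base class for all prmkit errors."""


class ConfigurationError(PrmkitError):
    """A simulation or analysis configuration is inconsistent or incomplete."""


class ParseError(PrmkitError):
    """A file on disk could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)


class InsufficientPeptidesError(PrmkitError):
    """Fewer proteotypic peptides were eligible than the required minimum."""


class LibraryError(PrmkitError):
    """A peptide is missing from the spectral library."""


class SaturationError(PrmkitError):
    """Observed divergence exceeds the range of the distance correction."""


class MotifError(PrmkitError):
    """A degenerate motif pattern is malformed."""
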