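"""Exception hierarchy shared across the pipeline."""


class LincnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LincnetError, ValueError):
    """A file did not match the expected tabular/standard format.

    Parsers raise this with the 1-based line number of the first
    offending line where applicable.
    """


class ConfigError(LincnetError, ValueError):
    """An invalid configuration (simulation or pipeline parameters)."""


class DomainError(LincnetError, ValueError):
    """Arguments outside an operation's mathematical domain."""


class CoordinateError(LincnetError, ValueError):
    """Genomic coordinates fall outside the referenced sequence."""


class UndefinedResultError(LincnetError, RuntimeError):
    """The requested quantity is undefined for this input (degenerate data),
    e.g. a power-law fit with fewer than three distinct degrees or a
    clustering with no variable feature."""
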