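"""Exception hierarchy used across the package."""


class KresolveError(Exception):
    """Base class for all package errors."""


class ParseError(KresolveError):
    """A sequence or graph file could not be parsed."""


class GraphFormatError(KresolveError):
    """A GFA file violates the fixed-overlap unitig graph contract."""


class PathError(KresolveError):
    """A path specification references a missing edge or node."""


class HashingError(KresolveError):
    """A sequence handed to the k-mer hasher contains non-ACGT symbols."""


class ConfigurationError(KresolveError):
    """Run parameters are inconsistent (exit code 2 at the CLI)."""


class GenerationError(KresolveError):
    """The synthetic-genome generator exhausted its rejection budget."""
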