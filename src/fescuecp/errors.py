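"""Exception hierarchy shared across modules."""


class FescueError(Exception):
    """Base class for all package errors."""


class InputError(FescueError):
    """Malformed or inconsistent user input (alignments, tables, labels)."""


class SizingError(FescueError):
    """A synthetic profile cannot be realised within its stated dimensions."""


class ParseError(InputError):
    """A file could not be parsed; message carries the offending record."""


class AmbiguousAmplificationError(FescueError):
    """A primer binds a template at more than one site."""


class SaturationError(FescueError):
    """A distance estimator's logarithm argument became non-positive."""


class UndefinedIndexError(FescueError):
    """Similarity index requested with zero total polymorphic loci."""


class ConfigurationError(FescueError):
    """Invalid parameter combination (e.g. overlapping genotyping windows)."""
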