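"""Typed exceptions shared across the pipeline stages."""


class FdmineError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FdmineError, ValueError):
    """A configuration object violates its invariants."""


class CorpusFormatError(FdmineError, ValueError):
    """An input file is missing mandatory structure (columns, keys)."""


class VectorizationError(FdmineError, ValueError):
    """The corpus cannot be vectorized (e.g. every document is empty)."""


class DegenerateInputError(FdmineError, ValueError):
    """A vector violates a distance metric's preconditions (zero vector for
    cosine, constant vector for correlation, empty support for Jaccard or
    Bray-Curtis).  Raised instead of silently propagating NaN."""


class DivergenceError(FdmineError, RuntimeError):
    """Autoencoder training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")
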