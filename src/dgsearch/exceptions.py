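"""Exception hierarchy for dgsearch."""


class DgsError(Exception):
    """Base class for all dgsearch errors."""


class ConfigurationError(DgsError, ValueError):
    """A configuration object violates its invariants."""


class CoordinateError(DgsError, ValueError):
    """Genomic coordinates fall outside the simulated or annotated genome."""


class UndefinedNoiseError(DgsError, ValueError):
    """Profile noise is undefined (fewer than two probes with a usable difference)."""


class InsufficientDataError(DgsError, ValueError):
    """Too few observations for the requested statistical operation."""


class UndefinedAUCError(DgsError, ValueError):
    """AUC is undefined (single-class labels or a constant feature)."""


class ConvergenceError(DgsError, RuntimeError):
    """Iterative fit failed to converge; carries the last iterate and delta."""

    def __init__(self, message, last_iterate=None, delta=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.delta = delta


class FileFormatError(DgsError, ValueError):
    """Malformed input file; message carries the file and line number."""
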