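"""Exception types shared across the package."""


class GRNBenchError(Exception):
    """Base class for grnbench errors."""


class DegenerateSignalError(GRNBenchError, ValueError):
    """Raised when the noise-free signal is rank deficient (smallest singular value 0)."""


class NumericalError(GRNBenchError, RuntimeError):
    """Raised when a linear solve or decomposition fails on a named object."""
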