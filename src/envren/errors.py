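"""Exception types shared across the package."""


class EnvrenError(Exception):
    """Base class for all envren-specific errors."""


class InvalidBandError(EnvrenError, ValueError):
    """A requested frequency band is empty or falls outside (0, fs/2)."""


class DegenerateEnvelopeError(EnvrenError, ValueError):
    """An envelope has (numerically) zero variance, e.g. a pure tone."""


class IllConditionedError(EnvrenError, ArithmeticError):
    """The renormalization denominator is undefined (SNR_ampl <= 1)."""


class InsufficientDataError(EnvrenError, ValueError):
    """Too few samples retained to estimate noise statistics."""


class DegenerateFitError(EnvrenError, RuntimeError):
    """HMM state collapse: the two emission means are indistinguishable."""


class LayoutMismatchError(EnvrenError, ValueError):
    """Recordings do not share channel layout or sampling rate."""
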