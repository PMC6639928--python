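"""Exception types shared across the package."""


class PondburstError(Exception):
    """Base class for all pondburst errors."""


class InvalidConfigError(PondburstError, ValueError):
    """A simulation or pipeline configuration value is out of range."""


class InvalidInputError(PondburstError, ValueError):
    """An input array/table violates a precondition of an operation."""


class InvalidTemplateError(PondburstError, ValueError):
    """A species call template cannot be synthesized (e.g. above Nyquist)."""


class UndefinedSNRError(PondburstError, ZeroDivisionError):
    """SNR requested with zero noise RMS."""
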