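"""Exception hierarchy.

Every error raised by the library derives from :class:`RepeatburstError`
so callers (and the CLI) can distinguish our failures from genuine bugs.
"""


class RepeatburstError(Exception):
    """Base class for all repeatburst errors."""


class InputError(RepeatburstError, ValueError):
    """An argument violates a documented precondition."""


class SaturationError(InputError):
    """Requested divergence would exceed the sub-saturation bound (0.75)."""


class PlacementError(RepeatburstError):
    """Copies could not be placed in the background without overlap."""


class InsufficientDataError(InputError):
    """Too few observations for the requested computation."""


class DegenerateColumnError(InputError):
    """An expression column has zero total rate and cannot be TPM-normalised."""


class UndefinedTauError(InputError):
    """Tau is undefined for an all-zero expression vector."""


class ConfigError(RepeatburstError):
    """A pipeline configuration file is invalid; message names the key."""
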