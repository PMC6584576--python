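"""Exception types shared across the pipeline."""


class UvlinkerError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(UvlinkerError, ValueError):
    """Invalid simulation or analysis configuration."""


class InputError(UvlinkerError, ValueError):
    """Malformed or inconsistent input data."""


class PairingError(InputError):
    """Mate files disagree in record count or read ids."""


class FrameError(InputError):
    """CDS length incompatible with its protein alignment row."""


class ConsistencyError(InputError):
    """CDS translation disagrees with the supplied protein sequence."""


class SaturationError(UvlinkerError, ValueError):
    """Divergence proportion at or beyond the correctable range (p >= 3/4)."""


class NormalizationError(UvlinkerError, ValueError):
    """No eligible windows to estimate a coverage scale factor from."""
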