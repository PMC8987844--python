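"""Exception hierarchy shared across the pipeline."""


class TilecoverError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TilecoverError):
    """Invalid tiling, training, or pipeline configuration."""


class DatasetError(TilecoverError):
    """Dataset construction failed (e.g. a class emptied out by filtering)."""


class SamplingError(TilecoverError):
    """Not enough material to draw the requested sample."""


class GenerationError(TilecoverError):
    """Synthetic scene generation could not satisfy the requested spec."""
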