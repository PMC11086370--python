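"""Exception taxonomy shared across the pipeline stages."""


class VocimsError(Exception):
    """Base class for all package errors."""


class ConfigError(VocimsError):
    """Invalid configuration value (dimensions, counts, thresholds, fold counts)."""


class WindowError(VocimsError):
    """A crop or RIP-line window selects nothing or lies outside the axes."""


class ShapeError(VocimsError):
    """Array shapes or axis lengths do not match."""


class CohortError(VocimsError):
    """Samples of a cohort are mutually inconsistent (heterogeneous axes, bad labels)."""


class ParseError(VocimsError):
    """A manifest or spectrum file could not be read as specified."""


class StratificationError(VocimsError):
    """A training split does not contain both classes."""


class InputError(VocimsError):
    """Degenerate statistical input (empty group, single class)."""
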