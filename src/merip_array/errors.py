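"""Exception hierarchy shared across the pipeline."""


class MeripArrayError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MeripArrayError):
    """Malformed input file (bad dialect, bad value, broken invariant on disk)."""


class ConfigError(MeripArrayError):
    """Invalid configuration (thresholds, simulation parameters, paths)."""


class AnalysisError(MeripArrayError):
    """A computation cannot proceed on this input (empty set, degenerate design)."""


class NumericError(MeripArrayError):
    """Non-finite or out-of-domain numeric input."""
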