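"""Exception types shared across the package."""


class FlightLearnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FlightLearnError):
    """Invalid configuration: unknown labels, bad thresholds, singular optics."""


class DataError(FlightLearnError):
    """Malformed input data: non-monotone time stamps, short traces, bad blocks."""
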