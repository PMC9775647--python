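"""Exception hierarchy shared across hepix modules."""


class HepixError(Exception):
    """Base class for all hepix errors."""


class ConfigError(HepixError, ValueError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataError(HepixError, ValueError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


class FormatError(DataError):
    """Raster file violates the expected format (bit depth, shape, channels)."""


class EmptyStratumError(DataError):
    """A resampling stratum contains no eligible pixels."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic."""
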