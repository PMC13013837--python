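"""Exception types shared across the pipeline."""


class TfapError(Exception):
    """Base class for all package errors."""


class ConfigError(TfapError, ValueError):
    """Invalid configuration value or combination."""


class FitError(TfapError, ValueError):
    """Model fit failed or produced an out-of-contract result."""


class NormalizationError(TfapError, ValueError):
    """A stratum required for normalization is missing."""


class MissingControlError(NormalizationError):
    """No control observations available for a required stratum."""


class DegenerateDataError(TfapError, ValueError):
    """Input data carry no usable variation for the requested statistic."""
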