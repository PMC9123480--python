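"""Exception and warning types shared across the package."""


class FluorlockError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FluorlockError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class ConfigError(FluorlockError, ValueError):
    """Inconsistent run configuration (e.g. stream/demodulator rate mismatch)."""


class CorruptInputError(FluorlockError, ValueError):
    """Input samples contain non-finite or otherwise unusable values."""


class DataFormatError(FluorlockError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class InsufficientDataError(FluorlockError, ValueError):
    """Too few usable records to carry out the requested analysis."""


class DegenerateDesignError(FluorlockError, ValueError):
    """The calibration design cannot identify the model (e.g. a single
    distinct concentration, or all concentrations zero)."""


class ClippingWarning(UserWarning):
    """More than an acceptable fraction of simulated samples hit the ADC rails."""


class NarrowbandWarning(UserWarning):
    """The modulation frequency is too close to the lock-in passband for
    clean synchronous detection."""
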