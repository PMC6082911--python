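"""Exception hierarchy for thmap."""


class THError(Exception):
    """Base class for all thmap errors."""


class THConfigurationError(THError):
    """Missing or inconsistent metadata / configuration (scan rate, direction, C_T...)."""


class THDataError(THError):
    """Malformed trace data (non-monotone temperature, too few points...)."""


class BaselineError(THError):
    """Baseline ranges invalid or baseline lines degenerate within the transition."""


class UndefinedTmError(THError):
    """The fraction-unfolded curve never crosses 0.5."""


class IntegrationError(THError):
    """Kinetic ODE integration failed; message carries solver diagnostics."""


class UndefinedOrderError(THError):
    """Effective reaction order requested where the total rate is (numerically) zero."""
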