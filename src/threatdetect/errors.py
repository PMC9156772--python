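"""Exception hierarchy used across the package."""


class ThreatDetectError(Exception):
    """Base class for package errors."""


class ConfigError(ThreatDetectError, ValueError):
    """Invalid design, observer, or analysis configuration."""


class ContractError(ThreatDetectError, ValueError):
    """An operation was called on inputs that violate its contract."""


class InsufficientDataError(ThreatDetectError, ValueError):
    """Not enough data to compute the requested quantity (e.g. < 4 reversals)."""
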