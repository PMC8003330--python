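"""Exception hierarchy shared across the package."""


class GlyatkinError(Exception):
    """Base class for all package errors."""


class ValidationError(GlyatkinError, ValueError):
    """Invalid parameter, concentration, or malformed input data."""


class DesignError(ValidationError):
    """Experimental design cannot identify the requested parameters."""


class ConfigError(ValidationError):
    """Malformed or unknown configuration entry."""


class ConvergenceError(GlyatkinError, RuntimeError):
    """Nonlinear regression failed to converge after all restarts."""


class ExtractionError(GlyatkinError, RuntimeError):
    """No acceptable linear window could be found in a time course."""


class IntegrationError(GlyatkinError, RuntimeError):
    """Progress-curve integration violated a conservation cap."""
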