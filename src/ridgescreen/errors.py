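"""Exception hierarchy shared across the package."""


class RidgescreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RidgescreenError, ValueError):
    """Invalid user-supplied configuration (bad correlation, grids, roles...)."""


class EstimationError(RidgescreenError, RuntimeError):
    """A model fit could not be carried out (rank deficiency, degenerate data)."""


class ValidationError(RidgescreenError, ValueError):
    """Malformed input tables or scenario files."""
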