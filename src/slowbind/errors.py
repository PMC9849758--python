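"""Exception hierarchy."""


class SlowbindError(Exception):
    """Base class for all package errors."""


class ConfigError(SlowbindError):
    """Invalid assay definition, config file, or parameter value."""


class SimulationError(SlowbindError):
    """The kinetic ODE integrator failed for a named curve."""


class FitError(SlowbindError):
    """A curve or dose-response fit could not be set up."""
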