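"""Exception types shared across the simulator."""


class ParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class StabilityError(ValueError):
    """A requested time step violates the explicit-Euler stability bound."""


class ConfigError(ValueError):
    """A run configuration file is malformed or contains unknown keys."""
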