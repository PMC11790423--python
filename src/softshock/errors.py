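"""Exception hierarchy for the simulator."""


class SoftShockError(Exception):
    """Base class for package errors."""


class ConfigError(SoftShockError, ValueError):
    """Invalid configuration or argument."""


class ElementInversionError(SoftShockError, RuntimeError):
    """A cell reached a non-positive volume ratio (det F <= 0)."""

    def __init__(self, message: str = "element inversion: det F <= 0", cells=None):
        super().__init__(message if cells is None else f"{message} at cells {cells}")
        self.cells = cells


class LossOfHyperbolicityError(SoftShockError, RuntimeError):
    """The acoustic tensor produced strongly negative or complex squared speeds."""

    def __init__(self, message: str = "loss of hyperbolicity", cells=None):
        super().__init__(message if cells is None else f"{message} at cells {cells}")
        self.cells = cells
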