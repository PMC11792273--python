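"""Exception types shared across the package."""


class ScreentrialError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ScreentrialError, ValueError):
    """An argument violates a precondition; the message names the field."""


class ConfigurationError(ScreentrialError, ValueError):
    """A design object (thresholds, allocation spec, trial config) is invalid.

    ``defects`` collects every problem found so a user can fix a config file
    in one pass.
    """

    def __init__(self, defects):
        if isinstance(defects, str):
            defects = [defects]
        self.defects = list(defects)
        super().__init__("; ".join(self.defects))


class SchemaError(ScreentrialError, ValueError):
    """A recorded participant table is missing columns or has unknown values."""

    def __init__(self, defects):
        if isinstance(defects, str):
            defects = [defects]
        self.defects = list(defects)
        super().__init__("; ".join(self.defects))


class SequencingError(ScreentrialError, RuntimeError):
    """An operation was called before its prerequisite step (e.g. outcomes
    requested before allocation)."""
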