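"""Exception hierarchy for shrnakit."""


class ShrnakitError(Exception):
    """Base class for all shrnakit errors."""


class ConfigError(ShrnakitError):
    """A configuration value violates its contract; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid config field '{field}': {message}")


class ParseError(ShrnakitError):
    """An input file or sequence could not be parsed; carries context."""


class DegenerateFitError(ShrnakitError):
    """A spike-in regression could not produce a usable calibration."""


class DesignError(ShrnakitError):
    """A paired design is inconsistent with itself or with the data matrix."""
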