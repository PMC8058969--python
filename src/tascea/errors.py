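"""Exception types shared across the package."""


class InputDomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(ValueError):
    """A scenario or run configuration is internally inconsistent."""


class ScenarioValidationError(ValueError):
    """A scenario file failed validation; carries the full list of violations."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("scenario validation failed:\n" + "\n".join(f"  - {e}" for e in self.errors))
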