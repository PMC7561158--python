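"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class SchemaError(ValueError):
    """A table does not match its documented column dictionary.

    Carries the full list of violations so a caller sees every problem at
    once rather than fixing them one by one.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "schema validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. one outcome class absent)."""


class UnsupportedOperationError(TypeError):
    """The operation is not defined for this model family."""
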