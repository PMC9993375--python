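"""Exception types used across the package."""


class ValidationError(ValueError):
    """A parameter or configuration value violates a model invariant.

    ``violations`` carries one message per violated invariant so that a
    config load can report every problem at once rather than the first.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class FitError(RuntimeError):
    """A survival-model fit could not be computed (no events, divergence)."""
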