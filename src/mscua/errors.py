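"""Exception types shared across the package."""


class MSCUAError(Exception):
    """Base class for all package errors."""


class ValidationError(MSCUAError):
    """A parameter, table or configuration failed validation.

    ``errors`` carries the individual messages when several violations are
    collected at once (configuration loading is not fail-fast).
    """

    def __init__(self, message, errors=None):
        super().__init__(message)
        self.errors = list(errors) if errors else [message]


class InfeasibleMomentsError(ValidationError):
    """Requested (mean, se) pair is outside the support of the fitted family."""


class UnspecifiedInputError(ValidationError):
    """A study-input field required for solving was never filled in."""
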