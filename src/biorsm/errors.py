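"""Exception hierarchy shared across the package."""


class BiorsmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BiorsmError, ValueError):
    """A user-supplied specification (factors, terms, goals, paths) is invalid."""


class SingularModelError(BiorsmError, ValueError):
    """The model matrix is rank deficient; names the collinear terms."""

    def __init__(self, terms):
        self.terms = tuple(terms)
        super().__init__(
            "model matrix is singular; collinear terms: " + ", ".join(self.terms)
        )


class DomainError(BiorsmError, ValueError):
    """An argument lies outside the mathematical domain of the operation."""


class FitConvergenceError(BiorsmError, RuntimeError):
    """A nonlinear fit failed to converge; carries the optimizer diagnostic."""
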