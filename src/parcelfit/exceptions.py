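"""Exception hierarchy shared across the package."""


class ParcelfitError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ParcelfitError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ParcelfitError, ValueError):
    """Input is structurally valid but degenerate (e.g. an all-zero matrix)."""


class DivergenceError(ParcelfitError, RuntimeError):
    """Numerical integration produced a non-finite state."""


class UndefinedCorrelationError(ParcelfitError, ValueError):
    """A Pearson correlation is undefined because one input is constant."""


class FormatError(ParcelfitError, ValueError):
    """A text artifact on disk does not match the expected layout."""


class DependencyError(ParcelfitError, RuntimeError):
    """A pipeline stage was invoked before the stage it depends on."""
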