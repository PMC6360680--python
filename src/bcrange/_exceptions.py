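"""Exception types shared across the package."""


class BcrangeError(Exception):
    """Base class for package-specific errors."""


class ParameterError(BcrangeError, ValueError):
    """A user-supplied parameter is outside its admissible range."""


class GenerationError(BcrangeError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class DegenerateModelError(BcrangeError, ValueError):
    """The decomposition is degenerate (no orthogonal or predictive signal)."""


class DegenerateGroupError(BcrangeError, ValueError):
    """A group's score cloud is too degenerate to fit a confidence ellipse."""


class InputError(BcrangeError, ValueError):
    """A feature table or file input violates its invariants."""
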