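"""Exception types shared across the package."""


class PvrdaError(Exception):
    """Base class for all package-specific errors."""


class NewickFormatError(PvrdaError, ValueError):
    """Raised when tree text cannot be parsed."""


class ValidationError(PvrdaError, ValueError):
    """Raised when an input violates a documented precondition."""


class SpeciesMismatchError(ValidationError):
    """Raised when species sets disagree across input tables/trees.

    Carries the symmetric difference so the caller can report exactly
    which names are missing from which side.
    """

    def __init__(self, only_left, only_right, left_name="first input",
                 right_name="second input"):
        self.only_left = sorted(only_left)
        self.only_right = sorted(only_right)
        parts = []
        if self.only_left:
            parts.append(f"only in {left_name}: {', '.join(self.only_left)}")
        if self.only_right:
            parts.append(f"only in {right_name}: {', '.join(self.only_right)}")
        super().__init__("species sets differ; " + "; ".join(parts))


class ConvergenceError(PvrdaError, RuntimeError):
    """Raised when a numeric optimisation fails from every start point."""

    def __init__(self, message, best_point=None, best_value=None,
                 gradient_norm=None):
        super().__init__(message)
        self.best_point = best_point
        self.best_value = best_value
        self.gradient_norm = gradient_norm
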