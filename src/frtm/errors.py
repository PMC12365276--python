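"""Exception hierarchy shared across the package."""


class FrtmError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FrtmError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SingularityError(DomainError):
    """Evaluation requested at a singular point of the weight function."""


class RankDeficiencyError(FrtmError, ValueError):
    """A column collapsed during orthogonalization (numerically dependent input)."""

    def __init__(self, column: int, norm_ratio: float):
        self.column = column
        self.norm_ratio = norm_ratio
        super().__init__(
            f"column {column} collapsed during orthogonalization "
            f"(post/pre projection norm ratio {norm_ratio:.3e}); "
            "the input is numerically rank-deficient — lower the maximum order "
            "or change the fractional order alpha"
        )


class CapacityError(FrtmError, ValueError):
    """Payload exceeds the embedding capacity of the configuration."""


class DegenerateNormalizationError(FrtmError, ValueError):
    """A constant signal cannot be min-max normalized for the angular-field mapping."""


class FormatError(FrtmError, ValueError):
    """A file did not parse as the expected plain-text format."""
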