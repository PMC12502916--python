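"""Exception types shared across the package."""


class PS5Error(Exception):
    """Base class for all package-specific errors."""


class SingularDesignError(PS5Error):
    """Raised when a regression design matrix is rank deficient.

    Parameters
    ----------
    columns : list of str
        Names of the columns implicated in the collinearity (the first
        column whose pivot vanishes in a QR factorization, together with
        any later ones).
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


class EmptySelectionError(PS5Error):
    """Raised when an operation requires a non-empty mediator set."""


class DataValidationError(PS5Error):
    """Raised when an input table violates the dataset contract."""
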