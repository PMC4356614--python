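"""Exception hierarchy shared across the package."""


class AlbunemiaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AlbunemiaError):
    """A configuration or input field failed validation; the message names the field."""


class DegenerateInputError(AlbunemiaError):
    """Input is constant, empty, or otherwise unusable for the requested fit."""


class MarkerMismatchError(AlbunemiaError):
    """Marker sets disagree between a model and the data it is applied to."""

    def __init__(self, missing=(), extra=()):
        self.missing = sorted(missing)
        self.extra = sorted(extra)
        super().__init__(
            f"marker mismatch: missing from data {self.missing}, "
            f"not in model {self.extra}"
        )


class EmptyPanelError(AlbunemiaError):
    """No complete observations remain; PCA is impossible."""


class DataConsistencyError(AlbunemiaError):
    """Rows contradict each other (e.g. a death recorded before a later visit)."""
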