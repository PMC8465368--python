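"""Exception types raised across the package."""


class FormatError(ValueError):
    """A contact-map file does not conform to the declared text format."""


class GranularityError(ValueError):
    """The time grid is too coarse to hold every observed time point."""


class DegenerateDataError(ValueError):
    """Input data carries no usable signal for the requested operation."""


class DivergenceError(RuntimeError):
    """The optimizer produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
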