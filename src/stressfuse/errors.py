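"""Exception hierarchy shared by all stressfuse modules."""


class StressFuseError(Exception):
    """Base class for all package errors."""


class InvalidConfiguration(StressFuseError):
    """A parameter combination violates an operation's preconditions."""


class DegenerateInput(StressFuseError):
    """Input is structurally valid but carries no usable information
    (constant series, empty segment, empty spectrogram, ...)."""


class EmptyResult(StressFuseError):
    """An operation that must produce at least one item produced none."""


class PeriodNotFound(EmptyResult):
    """No harmonic peak survived clipping of the autocorrelation."""


class ContextTooShort(StressFuseError):
    """Not enough signal surrounds the detected R waves for relocation."""


class NoFaceFound(EmptyResult):
    """The face detector returned no detection on any frame of a clip."""


class InvalidPosterior(StressFuseError):
    """A vector fed to the fusion stage is not a valid probability simplex."""


class DegenerateDataset(StressFuseError):
    """A training set does not contain at least two classes."""
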