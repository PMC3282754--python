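"""Exception hierarchy for placeburst."""


class PlaceburstError(Exception):
    """Base class for all placeburst errors."""


class LoadError(PlaceburstError):
    """Base class for session-loading failures."""


class MissingColumnError(LoadError):
    """A required column is absent from an input table."""


class EmptyFileError(LoadError):
    """An input table contains no data rows."""


class NonMonotonicTimeError(LoadError):
    """Timestamps are not strictly increasing."""


class OutOfArenaError(LoadError):
    """A tracked position lies outside the arena."""


class EmptyFieldError(PlaceburstError):
    """A place field (or its complement) is empty where a nonempty one is required."""


class UndefinedCoherenceError(PlaceburstError):
    """Spatial coherence is undefined (zero variance on one side of the correlation)."""


class GeometryMismatchError(PlaceburstError):
    """Two rate maps do not share grid geometry."""


class DegenerateOverlapError(PlaceburstError):
    """Too few jointly valid pixels, or zero variance, for a map correlation."""
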