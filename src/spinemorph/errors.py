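"""Exception types shared across the toolkit."""


class SpinemorphError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(SpinemorphError, ValueError):
    """An input violates a precondition (empty mask, out-of-range value, ...)."""


class MeasurementError(SpinemorphError):
    """A morphometric measurement could not be taken (e.g. empty column band)."""


class SizingError(SpinemorphError):
    """Requested phantom geometry does not fit the raster at the given spacing."""


class ParseError(SpinemorphError, ValueError):
    """A text record (YOLO detection file, CSV) failed to parse.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AlignmentError(SpinemorphError):
    """Per-vertebra inputs do not share the same set of vertebra ids."""


class UndefinedMetricError(SpinemorphError):
    """A metric is undefined for the given inputs (e.g. both masks empty)."""
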