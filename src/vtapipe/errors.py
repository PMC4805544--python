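"""Exception hierarchy.

Every rejected precondition in the package raises a named subclass of
:class:`VtapipeError` so callers can distinguish bad configuration, bad
data, and degenerate statistics without string matching.
"""


class VtapipeError(Exception):
    """Base class for all package errors."""


class ConfigError(VtapipeError, ValueError):
    """Invalid configuration value."""


class UnknownCueError(ConfigError):
    """Cue identifier outside {A, B, C, D}."""


class UnknownArchetypeError(ConfigError):
    """Response archetype outside the three supported classes."""


class DatasetValidationError(VtapipeError, ValueError):
    """A table violated the on-disk data contract.

    Carries the offending file and 0-based data-row index when known.
    """

    def __init__(self, message: str, *, file: str | None = None, row: int | None = None):
        self.file = file
        self.row = row
        loc = ""
        if file is not None:
            loc += f" [file={file}"
            loc += f", row={row}]" if row is not None else "]"
        super().__init__(message + loc)


class EmptyCountsError(VtapipeError, ValueError):
    """ROC normalization called with an empty count collection."""


class WindowError(VtapipeError, ValueError):
    """Analysis window falls outside the recorded trial span."""


class NoTrialsError(VtapipeError, ValueError):
    """No trials match the requested cue/session selection."""


class AmbiguousArchetypeError(VtapipeError):
    """Two clusters tie on the statistic that decides their archetype."""


class ZeroVarianceError(VtapipeError, ValueError):
    """A correlation or test statistic is undefined under zero variance."""


class MissingRewardError(VtapipeError, ValueError):
    """A reward-aligned analysis found trials without reward events."""


class SampleSizeError(VtapipeError, ValueError):
    """Too few units for the requested statistic."""


class BehaviorDesignError(VtapipeError, ValueError):
    """Factorial behavior design has empty cells."""

    def __init__(self, message: str, cells=None):
        self.cells = list(cells) if cells is not None else []
        super().__init__(message)


class WaveformError(VtapipeError, ValueError):
    """Waveform features violate the sign conventions of the criterion."""
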