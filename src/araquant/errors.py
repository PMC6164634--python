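"""Exception hierarchy for the araquant pipeline.

Each pipeline stage raises a distinct subclass so the CLI can map failures
to distinct exit codes and callers can catch narrowly.
"""


class AraquantError(Exception):
    """Base class for all araquant errors."""


class ContractViolation(AraquantError, ValueError):
    """An input violated a documented precondition (wrong shape, units, range)."""


class CalibrationError(AraquantError):
    """No usable quasi-static calibration window at the start of a stream."""


class DegenerateGeometryError(AraquantError):
    """Observation vectors are (near-)parallel; orientation is unobservable."""


class DegenerateTrajectoryError(AraquantError):
    """Trajectory has (near-)zero path length; arc parameterization undefined."""


class SegmentationError(AraquantError):
    """Phase segmentation failed; carries the candidate boundaries found."""

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = candidates if candidates is not None else []


class NoOnsetError(AraquantError):
    """Onset refinement found no rising cubic in the search window."""


class InsufficientSamplesError(AraquantError):
    """A phase is too short for the requested derivative/integral estimate."""


class QualityError(AraquantError):
    """Recording quality below threshold (gaps, dropped samples, bad rate)."""


class UndefinedCorrelationError(AraquantError):
    """Rank correlation undefined (zero variance in one of the variables)."""
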