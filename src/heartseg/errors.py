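"""Exception hierarchy.

Every failure mode of the toolchain raises a distinct, named error so callers
(and the CLI) can tell a bad input from a degenerate signal from a pipeline bug.
"""


class HeartsegError(Exception):
    """Base class for all heartseg errors."""


# --- audio / label I/O ---------------------------------------------------

class UnsupportedCodecError(HeartsegError):
    """Audio file is not a readable WAV PCM stream (e.g. MP3 with no decoder)."""


class EmptyAudioError(HeartsegError):
    """Audio stream contains zero samples."""


class MalformedLabelError(HeartsegError):
    """Label-track line is not three tab-separated fields with numeric times."""


class InvalidIntervalError(HeartsegError):
    """Interval has start >= end or negative start."""


class UnknownLabelError(HeartsegError):
    """Label string is not one of S1/systole/S2/diastole (case-sensitive)."""


class InvalidSegmentationError(HeartsegError):
    """A CycleSegmentation violates its structural invariants."""


# --- preprocessing -------------------------------------------------------

class SilentInputError(HeartsegError):
    """Signal is identically zero; standardization is undefined."""


class InvalidBandError(HeartsegError):
    """Band-pass edges are not 0 < low < high < Nyquist."""


class FrameTooLongError(HeartsegError):
    """Analysis frame is longer than the signal."""


class InsufficientCyclesError(HeartsegError):
    """Fewer complete cardiac cycles than the operation requires."""


# --- segmentation --------------------------------------------------------

class NoPeaksError(HeartsegError):
    """No candidate envelope peaks above threshold (e.g. silence)."""


class DegenerateSegmentationError(HeartsegError):
    """Outlier filtering or labeling left nothing usable."""


class SequencingError(HeartsegError):
    """S1/S2 onsets do not alternate; carries the offending cycle index."""

    def __init__(self, message: str, cycle_index: int | None = None):
        super().__init__(message)
        self.cycle_index = cycle_index


# --- features ------------------------------------------------------------

class IntervalOutsideRecordingError(HeartsegError):
    """Requested interval does not lie within the recording span."""


class IntervalTooShortError(HeartsegError):
    """Segment shorter than one analysis frame."""


# --- synthesis -----------------------------------------------------------

class InvalidConfigError(HeartsegError):
    """Synthetic PCG configuration violates its invariants."""


class UnknownPhaseError(HeartsegError):
    """Murmur phase must be SYSTOLE or DIASTOLE."""


# --- pipeline ------------------------------------------------------------

class PipelineStageError(HeartsegError):
    """A pipeline stage failed; names the stage for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class ValidationInputError(HeartsegError):
    """Heart-rate cross-validation inputs are unmatched or too small."""
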