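"""Signal conditioning ahead of S1/S2 detection.

Standardization (DC removal + peak normalization, the "amplification" step
that makes small stethoscope signals fill the display), a zero-phase
band-pass to reject breathing rumble and high-frequency hiss, the average
Shannon-energy envelope that the peak picker runs on, and edge trimming so
every output starts on an S1 onset and ends on a complete cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .audio_io import AudioRecording, CycleSegmentation
from .errors import (
    FrameTooLongError,
    InsufficientCyclesError,
    InvalidBandError,
    SilentInputError,
)

__all__ = [
    "Envelope",
    "standardize",
    "bandpass",
    "shannon_envelope",
    "trim_partial_cycles",
    "DEFAULT_BAND_HZ",
    "DEFAULT_FRAME_LEN_S",
    "DEFAULT_FRAME_HOP_S",
]

# Default detection band: covers S1/S2 energy (both sounds live well below
# ~400 Hz) while cutting sub-25 Hz breathing/motion rumble.
DEFAULT_BAND_HZ = (25.0, 400.0)
DEFAULT_FRAME_LEN_S = 0.02
DEFAULT_FRAME_HOP_S = 0.01


@dataclass(frozen=True)
class Envelope:
    """Frame-averaged Shannon energy of a standardized PCG.

    ``values[k]`` is the average of ``-x^2 ln(x^2)`` over the frame starting
    at ``k * frame_hop_s``; ``t0_s`` is the center time of frame 0.
    """

    values: np.ndarray
    frame_hop_s: float
    frame_len_s: float
    t0_s: float

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if self.frame_hop_s <= 0:
            raise ValueError("frame_hop_s must be positive")
        if self.frame_len_s < self.frame_hop_s:
            raise ValueError("frame_len_s must be >= frame_hop_s")
        if values.size and (not np.all(np.isfinite(values)) or values.min() < 0):
            raise ValueError("envelope values must be finite and nonnegative")

    def times(self) -> np.ndarray:
        """Center time of every frame."""
        return self.t0_s + self.frame_hop_s * np.arange(self.values.size)

    def time_of(self, index: int | float) -> float:
        """Center time of a (possibly fractional) frame index."""
        return self.t0_s + self.frame_hop_s * float(index)

    def index_of(self, time_s: float) -> int:
        """Nearest frame index to a time, clipped to the envelope span."""
        k = int(round((time_s - self.t0_s) / self.frame_hop_s))
        return min(max(k, 0), self.values.size - 1)


def standardize(recording: AudioRecording) -> AudioRecording:
    """Remove DC offset, then peak-normalize so ``max |x| == 1``.

    Idempotent to float tolerance; raises :class:`SilentInputError` on an
    identically zero signal.
    """
    x = recording.samples - recording.samples.mean()
    peak = np.abs(x).max()
    if peak == 0.0:
        raise SilentInputError("signal is identically zero after DC removal")
    return replace(recording, samples=x / peak)


def bandpass(
    recording: AudioRecording,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> AudioRecording:
    """Zero-phase 4th-order Butterworth band-pass; length and rate preserved."""
    nyq = recording.sample_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidBandError(
            f"need 0 < low < high < Nyquist ({nyq} Hz), got ({low_hz}, {high_hz})"
        )
    # order-2 sections run forward and backward -> 4th-order zero-phase response
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=recording.sample_rate,
                     output="sos")
    y = sps.sosfiltfilt(sos, recording.samples)
    return replace(recording, samples=y)


def shannon_envelope(
    recording: AudioRecording,
    frame_len_s: float = DEFAULT_FRAME_LEN_S,
    frame_hop_s: float = DEFAULT_FRAME_HOP_S,
) -> Envelope:
    """Average Shannon energy ``-x^2 ln(x^2)`` over sliding frames.

    Shannon energy emphasizes medium-intensity components, which suits PCG
    bursts: the transform is 0 at both ``x = 0`` (by continuity) and
    ``|x| = 1``, and peaks at ``|x| = e^{-1/2}``. Input is expected to be
    standardized (``|x| <= 1``) so the transform stays nonnegative.
    """
    fs = recording.sample_rate
    n = recording.samples.size
    frame_n = max(1, int(round(frame_len_s * fs)))
    hop_n = max(1, int(round(frame_hop_s * fs)))
    if frame_n > n:
        raise FrameTooLongError(
            f"frame of {frame_n} samples exceeds signal of {n} samples"
        )
    x2 = np.square(recording.samples)
    se = np.zeros_like(x2)
    nz = x2 > 0
    se[nz] = -x2[nz] * np.log(x2[nz])
    # |x| slightly above 1 (filter ringing) would go negative; clamp
    np.maximum(se, 0.0, out=se)
    csum = np.concatenate(([0.0], np.cumsum(se)))
    n_frames = 1 + (n - frame_n) // hop_n
    starts = hop_n * np.arange(n_frames)
    values = (csum[starts + frame_n] - csum[starts]) / frame_n
    np.maximum(values, 0.0, out=values)  # guard cumsum round-off
    return Envelope(
        values=values,
        frame_hop_s=hop_n / fs,
        frame_len_s=frame_n / fs,
        t0_s=frame_n / (2.0 * fs),
    )


def trim_partial_cycles(
    recording: AudioRecording, segmentation: CycleSegmentation
) -> tuple[AudioRecording, CycleSegmentation]:
    """Crop audio and labels to [first S1 onset, last complete cycle end).

    The returned labels are shifted so the first S1 starts at 0; every
    retained interval keeps its exact duration (microsecond-grid shift).
    Requires at least two complete cycles.
    """
    if segmentation.n_cycles < 2:
        raise InsufficientCyclesError(
            f"need >= 2 complete cycles to trim, got {segmentation.n_cycles}"
        )
    t0_us = segmentation.cycles[0].s1.start_us
    t1_us = segmentation.cycles[-1].diastole.end_us
    fs = recording.sample_rate
    i0 = int(round(t0_us * 1e-6 * fs))
    # ceil so the cropped audio always covers the last labeled interval
    i1 = min(recording.samples.size, int(np.ceil(t1_us * 1e-6 * fs - 1e-9)))
    trimmed = replace(recording, samples=recording.samples[i0:i1].copy())
    shifted = segmentation.shifted(-t0_us)
    return trimmed, shifted
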