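"""Parametric ground-truth phonocardiogram simulator.

Emulates the gross morphology of an auscultation recording: a quasi-periodic
train of two tone bursts per cardiac cycle (S1 at the cycle start, S2 at a
configurable systolic fraction), cycle-length jitter, and additive white
noise at a chosen SNR. Bursts are cosine-tapered (Tukey-windowed) sinusoids:
the taper keeps the spectrum clean while the window's exact support gives
unambiguous ground-truth onsets for boundary-error scoring — a window with
infinite tails would leave "the" onset undefined.

Truth labels follow the four-state convention: systole = S1 onset to S2
onset, diastole = S2 onset to the next S1 onset, with S1/S2 marking the
burst supports. All label times sit on the microsecond grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import tukey

from .audio_io import (
    AudioRecording,
    CardiacCycle,
    CycleSegmentation,
    SegmentInterval,
    SegmentState,
    us_to_seconds,
)
from .errors import InvalidConfigError, UnknownPhaseError

__all__ = ["SyntheticPCGConfig", "generate_pcg", "add_murmur"]

_US = 1_000_000
_TUKEY_ALPHA = 0.4  # cosine-taper fraction of each burst


@dataclass(frozen=True)
class SyntheticPCGConfig:
    """Generative parameters of the simulated PCG.

    Defaults describe a healthy adult at rest: 72 bpm, S1 slightly longer
    and louder than S2 (S1 0.12 s / 80 Hz vs S2 0.10 s / 110 Hz, amplitude
    ratio 1.3), S2 onset at 35% of the cycle, 1% cycle-length jitter.
    ``snr_db=None`` (or +inf) disables noise.
    """

    heart_rate_bpm: float = 72.0
    duration_s: float = 60.0
    s1_duration_s: float = 0.12
    s2_duration_s: float = 0.10
    s1_freq_hz: float = 80.0
    s2_freq_hz: float = 110.0
    s2_onset_fraction: float = 0.35
    s1_s2_amplitude_ratio: float = 1.3
    cycle_jitter_pct: float = 1.0
    snr_db: float | None = 20.0
    sample_rate_hz: int = 4000
    seed: int = 0

    def __post_init__(self):
        if not 40.0 <= self.heart_rate_bpm <= 200.0:
            raise InvalidConfigError("heart_rate_bpm must be in [40, 200]")
        period = 60.0 / self.heart_rate_bpm
        if self.duration_s <= 2 * period:
            raise InvalidConfigError("duration_s must exceed 2 cycles")
        if not 0 < self.s2_onset_fraction < 1:
            raise InvalidConfigError("s2_onset_fraction must be in (0, 1)")
        if self.s1_duration_s + self.s2_duration_s >= period:
            raise InvalidConfigError("burst durations must fit inside a cycle")
        if self.s1_duration_s >= self.s2_onset_fraction * period:
            raise InvalidConfigError("S1 burst must end before the S2 onset")
        if self.s2_onset_fraction * period + self.s2_duration_s >= period:
            raise InvalidConfigError("S2 burst must end before the next cycle")
        if self.s1_s2_amplitude_ratio <= 0:
            raise InvalidConfigError("s1_s2_amplitude_ratio must be positive")
        if self.cycle_jitter_pct < 0:
            raise InvalidConfigError("cycle_jitter_pct must be >= 0")
        if self.sample_rate_hz <= 0:
            raise InvalidConfigError("sample_rate_hz must be positive")
        nyq = self.sample_rate_hz / 2
        if self.s1_freq_hz >= nyq or self.s2_freq_hz >= nyq:
            raise InvalidConfigError("burst frequencies must be below Nyquist")


def generate_pcg(config: SyntheticPCGConfig) -> tuple[AudioRecording, CycleSegmentation]:
    """Simulate a PCG and its ground-truth four-state segmentation.

    Identical config (including seed) gives bit-identical audio and labels.
    Only cycles that complete within ``duration_s`` are synthesized and
    labeled.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    x = np.zeros(n)

    period_us = int(round(60.0 / config.heart_rate_bpm * _US))
    dur_us = int(round(config.duration_s * _US))
    jitter_sd_us = period_us * config.cycle_jitter_pct / 100.0

    # cycle boundaries on the microsecond grid
    bounds = [0]
    while True:
        d = period_us
        if jitter_sd_us > 0:
            d = int(round(period_us + jitter_sd_us * rng.standard_normal()))
            d = max(d, int(0.5 * period_us))  # keep cycles sane under big jitter
        nxt = bounds[-1] + d
        if nxt > dur_us:
            break
        bounds.append(nxt)
    if len(bounds) < 3:
        raise InvalidConfigError("duration too short for two complete cycles")

    a1 = 1.0
    a2 = 1.0 / config.s1_s2_amplitude_ratio
    cycles = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        cyc_us = b1 - b0
        s1_end_us = b0 + int(round(config.s1_duration_s * _US))
        s2_on_us = b0 + int(round(config.s2_onset_fraction * cyc_us))
        s2_end_us = s2_on_us + int(round(config.s2_duration_s * _US))
        _add_burst(x, fs, b0 / _US, config.s1_duration_s, config.s1_freq_hz, a1)
        _add_burst(x, fs, s2_on_us / _US, config.s2_duration_s, config.s2_freq_hz, a2)
        s1 = SegmentInterval(us_to_seconds(b0), us_to_seconds(s1_end_us), SegmentState.S1)
        systole = SegmentInterval(us_to_seconds(b0), us_to_seconds(s2_on_us),
                                  SegmentState.SYSTOLE)
        s2 = SegmentInterval(us_to_seconds(s2_on_us), us_to_seconds(s2_end_us),
                             SegmentState.S2)
        diastole = SegmentInterval(us_to_seconds(s2_on_us), us_to_seconds(b1),
                                   SegmentState.DIASTOLE)
        cycles.append(CardiacCycle(s1, systole, s2, diastole))

    if config.snr_db is not None and math.isfinite(config.snr_db):
        sig_rms = float(np.sqrt(np.mean(np.square(x))))
        noise_rms = sig_rms / (10.0 ** (config.snr_db / 20.0))
        x = x + noise_rms * rng.standard_normal(n)

    rec = AudioRecording(samples=x, sample_rate=fs, source_path=None)
    return rec, CycleSegmentation(tuple(cycles))


def _add_burst(
    x: np.ndarray, fs: int, onset_s: float, dur_s: float, freq_hz: float, amp: float
) -> None:
    i0 = int(round(onset_s * fs))
    m = int(round(dur_s * fs))
    i1 = min(i0 + m, x.size)
    if i1 <= i0:
        return
    t = np.arange(i1 - i0) / fs
    w = tukey(m, alpha=_TUKEY_ALPHA)[: i1 - i0]
    x[i0:i1] += amp * w * np.sin(2 * np.pi * freq_hz * t)


def add_murmur(
    recording: AudioRecording,
    truth: CycleSegmentation,
    band_hz: tuple[float, float] = (150.0, 600.0),
    rel_level: float = 0.2,
    phase: SegmentState = SegmentState.SYSTOLE,
    seed: int = 0,
) -> AudioRecording:
    """Add band-limited noise inside every systolic or diastolic interval.

    ``rel_level`` scales the murmur RMS relative to the recording RMS inside
    the chosen phase; 0 returns the input unchanged. Truth labels are not
    modified. Phases other than SYSTOLE/DIASTOLE raise
    :class:`UnknownPhaseError`.
    """
    if phase not in (SegmentState.SYSTOLE, SegmentState.DIASTOLE):
        raise UnknownPhaseError(f"murmur phase must be systole/diastole, got {phase!r}")
    if not 0 <= rel_level < 1:
        raise InvalidConfigError("rel_level must be in [0, 1)")
    if rel_level == 0:
        return recording
    lo, hi = band_hz
    nyq = recording.sample_rate / 2
    if not 0 < lo < hi < nyq:
        raise InvalidConfigError(f"murmur band must satisfy 0 < lo < hi < {nyq}")
    rng = np.random.default_rng(seed)
    fs = recording.sample_rate
    x = recording.samples.copy()
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    for c in truth.cycles:
        iv = c.systole if phase is SegmentState.SYSTOLE else c.diastole
        # same half-open sample convention as AudioRecording.slice_seconds
        i0 = max(0, int(np.ceil(iv.start_s * fs - 1e-9)))
        i1 = min(int(np.ceil(iv.end_s * fs - 1e-9)), x.size)
        if i1 - i0 < 8:
            continue
        seg_rms = float(np.sqrt(np.mean(np.square(x[i0:i1]))))
        noise = sps.sosfiltfilt(sos, rng.standard_normal(i1 - i0))
        nrms = float(np.sqrt(np.mean(np.square(noise))))
        if nrms == 0 or seg_rms == 0:
            continue
        x[i0:i1] += noise * (rel_level * seg_rms / nrms)
    return replace(recording, samples=x)
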