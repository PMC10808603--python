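"""Audio and label-track I/O, and the core time-interval types.

All time/format conventions live here:

* Times are seconds (float), intervals half-open ``[start, end)``; sample
  ``i`` covers ``[i/fs, (i+1)/fs)``.
* Label times are kept on an integer-microsecond grid — the same resolution
  as the 6-decimal Audacity label format — so that duration bookkeeping
  (systole + diastole == cycle) is exact integer arithmetic, not float
  summation.
* Canonical on-disk audio is WAV PCM; label tracks are Audacity's
  tab-separated ``start<TAB>end<TAB>label`` text format with the four
  case-sensitive state labels ``S1``, ``systole``, ``S2``, ``diastole``.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

from .errors import (
    EmptyAudioError,
    InvalidIntervalError,
    InvalidSegmentationError,
    MalformedLabelError,
    UnknownLabelError,
    UnsupportedCodecError,
)

__all__ = [
    "SegmentState",
    "AudioRecording",
    "SegmentInterval",
    "CardiacCycle",
    "CycleSegmentation",
    "read_audio",
    "write_audio",
    "read_label_track",
    "write_label_track",
    "seconds_to_us",
    "us_to_seconds",
]

_US = 1_000_000


def seconds_to_us(t: float) -> int:
    """Map a time in seconds onto the integer-microsecond label grid."""
    return int(round(t * _US))


def us_to_seconds(n: int) -> float:
    return n / _US


class SegmentState(str, enum.Enum):
    """The four cardiac-cycle states; values are the on-disk label strings."""

    S1 = "S1"
    SYSTOLE = "systole"
    S2 = "S2"
    DIASTOLE = "diastole"


_LABEL_TO_STATE = {s.value: s for s in SegmentState}


@dataclass(frozen=True)
class AudioRecording:
    """A mono PCG: full-scale samples in [-1, 1] plus sample rate in Hz."""

    samples: np.ndarray
    sample_rate: int
    source_path: str | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if samples.ndim != 1:
            raise ValueError("AudioRecording is mono: samples must be 1-D")
        if samples.size < 1:
            raise EmptyAudioError("recording has zero samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def slice_seconds(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples covering [start_s, end_s); sample i covers [i/fs, (i+1)/fs)."""
        fs = self.sample_rate
        i0 = max(0, int(np.ceil(start_s * fs - 1e-9)))
        i1 = min(self.samples.size, int(np.ceil(end_s * fs - 1e-9)))
        return self.samples[i0:i1]


@dataclass(frozen=True)
class SegmentInterval:
    """Half-open time interval [start_s, end_s) carrying a cardiac state."""

    start_s: float
    end_s: float
    state: SegmentState
    clipped: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.start_s < 0:
            raise InvalidIntervalError(f"start_s must be >= 0, got {self.start_s}")
        if not self.start_s < self.end_s:
            raise InvalidIntervalError(
                f"require start < end, got [{self.start_s}, {self.end_s})"
            )
        if not isinstance(self.state, SegmentState):
            raise UnknownLabelError(f"unknown state {self.state!r}")

    @property
    def duration_s(self) -> float:
        return us_to_seconds(self.duration_us)

    @property
    def start_us(self) -> int:
        return seconds_to_us(self.start_s)

    @property
    def end_us(self) -> int:
        return seconds_to_us(self.end_s)

    @property
    def duration_us(self) -> int:
        return self.end_us - self.start_us

    def shifted(self, offset_us: int) -> "SegmentInterval":
        """Translate in time by an integer number of microseconds."""
        return replace(
            self,
            start_s=us_to_seconds(self.start_us + offset_us),
            end_s=us_to_seconds(self.end_us + offset_us),
        )


@dataclass(frozen=True)
class CardiacCycle:
    """One heartbeat: S1 and S2 bursts embedded in systole and diastole.

    Systole runs from the S1 onset to the S2 onset, diastole from the S2
    onset to the next cycle's S1 onset, so the two phases tile the cycle
    exactly and S1/S2 are contained in their phases.
    """

    s1: SegmentInterval
    systole: SegmentInterval
    s2: SegmentInterval
    diastole: SegmentInterval

    def __post_init__(self):
        s1, sys_, s2, dia = self.s1, self.systole, self.s2, self.diastole
        for iv, want in ((s1, SegmentState.S1), (sys_, SegmentState.SYSTOLE),
                         (s2, SegmentState.S2), (dia, SegmentState.DIASTOLE)):
            if iv.state is not want:
                raise InvalidSegmentationError(
                    f"interval state {iv.state} where {want} expected"
                )
        if s1.start_s != sys_.start_s:
            raise InvalidSegmentationError("S1 and systole must share their onset")
        if s2.start_s != dia.start_s:
            raise InvalidSegmentationError("S2 and diastole must share their onset")
        if sys_.end_s != s2.start_s:
            raise InvalidSegmentationError("systole must end at the S2 onset")
        if s1.end_s > sys_.end_s:
            raise InvalidSegmentationError("S1 must be contained in systole")
        if s2.end_s > dia.end_s:
            raise InvalidSegmentationError("S2 must be contained in diastole")

    @property
    def start_s(self) -> float:
        return self.s1.start_s

    @property
    def end_s(self) -> float:
        return self.diastole.end_s

    @property
    def duration_us(self) -> int:
        return self.diastole.end_us - self.s1.start_us

    @property
    def duration_s(self) -> float:
        return us_to_seconds(self.duration_us)

    def intervals(self) -> list[SegmentInterval]:
        """The four intervals in canonical time order."""
        return [self.s1, self.systole, self.s2, self.diastole]


@dataclass(frozen=True)
class CycleSegmentation:
    """Time-ordered, non-overlapping cardiac cycles."""

    cycles: tuple[CardiacCycle, ...] = ()

    def __post_init__(self):
        cycles = tuple(self.cycles)
        object.__setattr__(self, "cycles", cycles)
        for k in range(1, len(cycles)):
            prev, cur = cycles[k - 1], cycles[k]
            if prev.end_s > cur.start_s:
                raise InvalidSegmentationError(
                    f"cycles {k - 1} and {k} overlap ({prev.end_s} > {cur.start_s})"
                )

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def contiguous(self) -> bool:
        """True when every diastole ends exactly at the next cycle's S1 onset."""
        return all(
            self.cycles[k - 1].diastole.end_us == self.cycles[k].s1.start_us
            for k in range(1, len(self.cycles))
        )

    def intervals(self) -> list[SegmentInterval]:
        """All intervals flattened in time order (S1, systole, S2, diastole per cycle)."""
        out: list[SegmentInterval] = []
        for c in self.cycles:
            out.extend(c.intervals())
        return out

    def shifted(self, offset_us: int) -> "CycleSegmentation":
        return CycleSegmentation(
            tuple(
                CardiacCycle(
                    c.s1.shifted(offset_us),
                    c.systole.shifted(offset_us),
                    c.s2.shifted(offset_us),
                    c.diastole.shifted(offset_us),
                )
                for c in self.cycles
            )
        )


# --------------------------------------------------------------------------
# audio files


def read_audio(path: str | os.PathLike) -> AudioRecording:
    """Read a WAV PCM file as a mono, float64, full-scale recording.

    Integer PCM is rescaled to [-1, 1]; float WAV passes through.
    Multi-channel input is mixed down by averaging channels. MP3 (or any
    non-WAV stream) raises :class:`UnsupportedCodecError` — no MP3 decoder
    is bundled.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"audio file not found: {path}")
    if os.path.getsize(path) == 0:
        raise EmptyAudioError(f"audio file is empty: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise UnsupportedCodecError(f"not a readable WAV PCM file: {path} ({exc})")
    if data.size == 0:
        raise EmptyAudioError(f"audio stream has zero samples: {path}")
    samples = _to_unit_scale(data)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioRecording(samples=samples, sample_rate=int(rate), source_path=path)


def _to_unit_scale(data: np.ndarray) -> np.ndarray:
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64)


def write_audio(recording: AudioRecording, path: str | os.PathLike) -> None:
    """Write as 16-bit PCM WAV."""
    x = np.clip(recording.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(os.fspath(path), recording.sample_rate, pcm)


# --------------------------------------------------------------------------
# Audacity label tracks


def write_label_track(segmentation: CycleSegmentation, path: str | os.PathLike) -> None:
    """Write an Audacity label track: ``start<TAB>end<TAB>label`` per interval.

    Times carry 6 decimal places; one line per interval in time order; the
    file is newline-terminated. An empty segmentation yields an empty file.
    """
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        for iv in segmentation.intervals():
            fh.write(f"{iv.start_s:.6f}\t{iv.end_s:.6f}\t{iv.state.value}\n")


def read_label_track(path: str | os.PathLike) -> CycleSegmentation:
    """Parse an Audacity label track back into a :class:`CycleSegmentation`.

    Inverse of :func:`write_label_track`: the round trip is bit-exact at
    6-decimal precision. Lines must be exactly three tab-separated fields;
    labels must be one of the four case-sensitive state strings; intervals
    must satisfy start < end and form whole S1/systole/S2/diastole cycles.
    """
    intervals: list[SegmentInterval] = []
    with open(os.fspath(path), "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise MalformedLabelError(
                    f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            s_str, e_str, label = fields
            try:
                start, end = float(s_str), float(e_str)
            except ValueError:
                raise MalformedLabelError(f"line {lineno}: non-numeric time")
            if label not in _LABEL_TO_STATE:
                raise UnknownLabelError(f"line {lineno}: unknown label {label!r}")
            if not start < end:
                raise InvalidIntervalError(
                    f"line {lineno}: start >= end ({start} >= {end})"
                )
            intervals.append(SegmentInterval(start, end, _LABEL_TO_STATE[label]))
    return _cycles_from_intervals(intervals)


_CYCLE_PATTERN = (
    SegmentState.S1,
    SegmentState.SYSTOLE,
    SegmentState.S2,
    SegmentState.DIASTOLE,
)


def _cycles_from_intervals(intervals: list[SegmentInterval]) -> CycleSegmentation:
    if len(intervals) % 4 != 0:
        raise InvalidSegmentationError(
            f"label track holds {len(intervals)} intervals; whole cycles need 4 each"
        )
    cycles = []
    for k in range(0, len(intervals), 4):
        chunk = intervals[k : k + 4]
        got = tuple(iv.state for iv in chunk)
        if got != _CYCLE_PATTERN:
            raise InvalidSegmentationError(
                f"cycle {k // 4}: states {[s.value for s in got]} do not form "
                "an S1/systole/S2/diastole cycle"
            )
        cycles.append(CardiacCycle(*chunk))
    return CycleSegmentation(tuple(cycles))
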