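"""Per-segment acoustic feature battery.

For every labeled segment (S1, systole, S2, diastole) of every cycle the
battery computes:

* durations (from the label times, exact on the microsecond grid);
* framed amplitude levels in dBFS (maxdb / mindb / meandb / middledb over
  20 ms frames, 10 ms hop, 0 dB = full scale after standardization);
* time-domain statistics on the raw segment samples (population moments,
  non-excess kurtosis, RMS, shape/impulse/margin factors, energy);
* frame-wise fundamental-frequency statistics from normalized
  autocorrelation (50–400 Hz search band, 40 ms frames, 10 ms hop, voicing
  threshold 0.3 on the autocorrelation peak);
* periodicity quality: jitter (%) over consecutive voiced-frame periods
  and a harmonics-to-noise ratio from the mean autocorrelation peak;
* the per-frame harmonic ratio (periodicity score in [0, 1]) summarized by
  mean/median/sd/max/min.

Features that are undefined on a segment (zero variance, no voiced frames,
too few periods) carry ``NaN`` as an explicit sentinel — never a silent 0 —
so summaries can exclude them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .audio_io import AudioRecording, CycleSegmentation, SegmentInterval
from .errors import (
    IntervalOutsideRecordingError,
    IntervalTooShortError,
)

__all__ = [
    "AMPLITUDE_FRAME_S",
    "AMPLITUDE_HOP_S",
    "F0_FRAME_S",
    "F0_HOP_S",
    "F0_BAND_HZ",
    "VOICING_THRESHOLD",
    "DB_FLOOR",
    "amplitude_features",
    "stat_features",
    "f0_features",
    "quality_features",
    "hr_ratio_features",
    "time_domain_features",
    "extract_all",
    "summarize_features",
    "FEATURE_COLUMNS",
]

AMPLITUDE_FRAME_S = 0.02
AMPLITUDE_HOP_S = 0.01
F0_FRAME_S = 0.04
F0_HOP_S = 0.01
F0_BAND_HZ = (50.0, 400.0)
VOICING_THRESHOLD = 0.3
DB_FLOOR = -120.0

_STAT_KEYS = [
    "absomean", "STD", "skew", "kurt", "max", "min", "peak2valley",
    "RMS", "shapefactor", "impulsefactor", "marginfactor", "energy",
]
_F0_KEYS = [
    "first_f0", "middle_f0", "last_f0", "median_f0", "mean_f0",
    "f0variation", "f0skew", "f0kurt", "max_f0", "min_f0", "range_f0",
    "slope_start2max", "slope_max2end",
]
_QUALITY_KEYS = ["jitter", "HNR"]
_HR_KEYS = ["hr_mean", "hr_median", "hr_std", "hr_max", "hr_min"]
_AMP_KEYS = ["maxdb", "mindb", "meandb", "middledb"]

FEATURE_COLUMNS = (
    ["cycle", "state", "duration"]
    + _AMP_KEYS
    + _STAT_KEYS
    + _F0_KEYS
    + _QUALITY_KEYS
    + _HR_KEYS
)


def _segment_samples(recording: AudioRecording, interval: SegmentInterval) -> np.ndarray:
    # tolerate sub-sample overrun from time-grid <-> sample-grid rounding
    tol = 1.0 / recording.sample_rate
    if interval.start_s >= recording.duration_s or interval.end_s > recording.duration_s + tol:
        raise IntervalOutsideRecordingError(
            f"interval [{interval.start_s}, {interval.end_s}) outside recording "
            f"of {recording.duration_s:.6f} s"
        )
    return recording.slice_seconds(interval.start_s, interval.end_s)


def _frames(x: np.ndarray, frame_n: int, hop_n: int) -> np.ndarray:
    """Full frames inside x as a (n_frames, frame_n) view-copy."""
    n = x.size
    if n < frame_n:
        return np.empty((0, frame_n))
    n_frames = 1 + (n - frame_n) // hop_n
    idx = hop_n * np.arange(n_frames)[:, None] + np.arange(frame_n)[None, :]
    return x[idx]


# --------------------------------------------------------------------------
# amplitude (dBFS)


def amplitude_features(
    recording: AudioRecording, interval: SegmentInterval
) -> dict[str, float]:
    """Framed levels in dBFS: max/min/mean/median of per-frame 20*log10(RMS).

    Frames are 20 ms with 10 ms hop; a segment shorter than one frame is
    measured as a single whole-segment frame and flagged (``short_segment``).
    Silent frames are floored at -120 dB.
    """
    x = _segment_samples(recording, interval)
    fs = recording.sample_rate
    frame_n = max(1, int(round(AMPLITUDE_FRAME_S * fs)))
    hop_n = max(1, int(round(AMPLITUDE_HOP_S * fs)))
    short = x.size < frame_n
    frames = x[None, :] if short else _frames(x, frame_n, hop_n)
    rms = np.sqrt(np.mean(np.square(frames), axis=1))
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(rms)
    db = np.maximum(db, DB_FLOOR)
    return {
        "maxdb": float(db.max()),
        "mindb": float(db.min()),
        "meandb": float(db.mean()),
        "middledb": float(np.median(db)),
        "short_segment": bool(short),
    }


# --------------------------------------------------------------------------
# time-domain statistics


def stat_features(
    recording: AudioRecording, interval: SegmentInterval
) -> dict[str, float]:
    """Population-moment statistics and classical condition-monitoring
    factors on the raw segment samples.

    Kurtosis is non-excess (Gaussian baseline 3). Zero-variance segments
    report skew/kurt as NaN sentinels, never 0.
    """
    x = _segment_samples(recording, interval)
    if x.size < 2:
        raise IntervalTooShortError("stat features need >= 2 samples")
    mean = x.mean()
    absomean = float(np.mean(np.abs(x)))
    std = float(np.sqrt(np.mean((x - mean) ** 2)))
    rms = float(np.sqrt(np.mean(x**2)))
    xmax = float(x.max())
    xmin = float(x.min())
    peak = float(np.max(np.abs(x)))
    # zero-variance to float accumulation accuracy -> undefined moments
    if std > 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        skew = float(np.mean((x - mean) ** 3) / std**3)
        kurt = float(np.mean((x - mean) ** 4) / std**4)
    else:
        skew = float("nan")
        kurt = float("nan")
    sqrt_mean = float(np.mean(np.sqrt(np.abs(x))))
    return {
        "absomean": absomean,
        "STD": std,
        "skew": skew,
        "kurt": kurt,
        "max": xmax,
        "min": xmin,
        "peak2valley": xmax - xmin,
        "RMS": rms,
        "shapefactor": rms / absomean if absomean > 0 else float("nan"),
        "impulsefactor": peak / absomean if absomean > 0 else float("nan"),
        "marginfactor": peak / sqrt_mean**2 if sqrt_mean > 0 else float("nan"),
        "energy": float(np.sum(x**2)),
    }


# --------------------------------------------------------------------------
# fundamental frequency via normalized autocorrelation


def _frame_autocorr(
    x: np.ndarray, fs: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (f0, peak normalized autocorrelation, voiced flag).

    Frames are 40 ms / 10 ms hop; the lag search spans the 50–400 Hz band;
    the best lag is refined by parabolic interpolation. Frames whose peak
    normalized autocorrelation falls below 0.3 are unvoiced (f0 = NaN).
    Raises :class:`IntervalTooShortError` when not even one frame fits.
    """
    frame_n = int(round(F0_FRAME_S * fs))
    hop_n = max(1, int(round(F0_HOP_S * fs)))
    if x.size < frame_n:
        raise IntervalTooShortError(
            f"segment of {x.size} samples shorter than one {frame_n}-sample f0 frame"
        )
    frames = _frames(x, frame_n, hop_n)
    lo_lag = max(2, int(np.ceil(fs / F0_BAND_HZ[1])))
    hi_lag = min(frame_n - 2, int(np.floor(fs / F0_BAND_HZ[0])))
    if hi_lag <= lo_lag:
        raise IntervalTooShortError("sample rate too low for the f0 search band")

    n_frames = frames.shape[0]
    f0 = np.full(n_frames, np.nan)
    rpeak = np.zeros(n_frames)
    lags = np.arange(lo_lag, hi_lag + 1)
    for i in range(n_frames):
        fr = frames[i]
        # two normalizations of the lag-L product sum:
        #   biased   (by total frame energy)  — damps long lags, so noise
        #            cannot fake periodicity; drives voicing and lag choice
        #   unbiased (by the two windows' norms) — true periodicity
        #            strength at the lag; drives HNR / harmonic ratio
        rb = np.empty(lags.size)
        ru = np.empty(lags.size)
        e0 = np.dot(fr, fr)
        for j, lag in enumerate(lags):
            a = fr[:-lag]
            b = fr[lag:]
            dot = np.dot(a, b)
            rb[j] = dot / e0 if e0 > 0 else 0.0
            denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
            ru[j] = dot / denom if denom > 0 else 0.0
        rpeak[i] = float(ru.max())
        rb_best = rb.max()
        if rb_best >= VOICING_THRESHOLD:
            # prefer the smallest near-maximal lag: integer multiples of the
            # fundamental period correlate just as well (octave errors)
            jbest = int(np.argmax(rb))
            for j in range(rb.size):
                if rb[j] >= 0.95 * rb_best and _is_local_max(rb, j):
                    jbest = j
                    break
            lag = float(lags[jbest])
            if 0 < jbest < rb.size - 1:  # parabolic refinement
                denom = rb[jbest - 1] - 2 * rb[jbest] + rb[jbest + 1]
                if denom < 0:
                    lag += 0.5 * (rb[jbest - 1] - rb[jbest + 1]) / denom
            f0[i] = min(max(fs / lag, F0_BAND_HZ[0]), F0_BAND_HZ[1])
    voiced = ~np.isnan(f0)
    return f0, rpeak, voiced


def _is_local_max(r: np.ndarray, j: int) -> bool:
    left = r[j - 1] if j > 0 else -np.inf
    right = r[j + 1] if j < r.size - 1 else -np.inf
    return r[j] >= left and r[j] >= right


def f0_features(
    recording: AudioRecording, interval: SegmentInterval
) -> dict[str, float]:
    """Fundamental-frequency statistics over the segment's voiced frames.

    ``slope_start2max`` / ``slope_max2end`` are rise/decay rates of the f0
    track normalized by mean f0: (max_f0 - first_f0) per second from
    segment start to the max-f0 frame (and max to last), divided by
    mean_f0, so they are dimensionless. All-unvoiced segments report NaN
    sentinels throughout.
    """
    x = _segment_samples(recording, interval)
    f0, _, voiced = _frame_autocorr(x, recording.sample_rate)
    out = {k: float("nan") for k in _F0_KEYS}
    if not voiced.any():
        return out
    vidx = np.where(voiced)[0]
    vf0 = f0[vidx]
    out["first_f0"] = float(vf0[0])
    out["middle_f0"] = float(vf0[len(vf0) // 2])
    out["last_f0"] = float(vf0[-1])
    out["median_f0"] = float(np.median(vf0))
    mean_f0 = float(np.mean(vf0))
    out["mean_f0"] = mean_f0
    out["f0variation"] = float(np.sqrt(np.mean((vf0 - mean_f0) ** 2)))
    sd = out["f0variation"]
    if sd > 0:
        out["f0skew"] = float(np.mean((vf0 - mean_f0) ** 3) / sd**3)
        out["f0kurt"] = float(np.mean((vf0 - mean_f0) ** 4) / sd**4)
    out["max_f0"] = float(vf0.max())
    out["min_f0"] = float(vf0.min())
    out["range_f0"] = out["max_f0"] - out["min_f0"]
    # frame center times relative to the segment start
    imax = vidx[int(np.argmax(vf0))]
    t_max = F0_FRAME_S / 2 + F0_HOP_S * imax
    t_last = F0_FRAME_S / 2 + F0_HOP_S * vidx[-1]
    seg_dur = interval.duration_s
    if mean_f0 > 0:
        if t_max > 0:
            out["slope_start2max"] = (out["max_f0"] - out["first_f0"]) / t_max / mean_f0
        tail = max(seg_dur - t_max, t_last - t_max)
        if tail > 0:
            out["slope_max2end"] = (out["last_f0"] - out["max_f0"]) / tail / mean_f0
        else:
            out["slope_max2end"] = 0.0
    return out


def quality_features(
    recording: AudioRecording, interval: SegmentInterval
) -> dict[str, float]:
    """Jitter (%) and harmonics-to-noise ratio (dB) of the segment.

    Jitter = 100 * mean |P_{i+1} - P_i| / mean P over consecutive
    voiced-frame fundamental periods P = 1/f0; needs >= 2 voiced frames,
    else NaN. HNR = 10 log10(r / (1 - r)) with r the mean peak normalized
    autocorrelation — over voiced frames when any exist, otherwise over
    all frames so aperiodic segments still get a (negative) HNR.
    """
    x = _segment_samples(recording, interval)
    f0, rpeak, voiced = _frame_autocorr(x, recording.sample_rate)
    out = {"jitter": float("nan"), "HNR": float("nan")}
    if voiced.sum() >= 2:
        periods = 1.0 / f0[voiced]
        out["jitter"] = float(
            100.0 * np.mean(np.abs(np.diff(periods))) / np.mean(periods)
        )
    r = float(np.mean(rpeak[voiced])) if voiced.any() else float(np.mean(rpeak))
    r = min(max(r, 1e-6), 1.0 - 1e-6)
    out["HNR"] = float(10.0 * np.log10(r / (1.0 - r)))
    return out


def hr_ratio_features(
    recording: AudioRecording, interval: SegmentInterval
) -> dict[str, float]:
    """Per-frame harmonic ratio (peak normalized autocorrelation in the f0
    band, clipped to [0, 1]) summarized over all frames."""
    x = _segment_samples(recording, interval)
    _, rpeak, _ = _frame_autocorr(x, recording.sample_rate)
    hr = np.clip(rpeak, 0.0, 1.0)
    return {
        "hr_mean": float(hr.mean()),
        "hr_median": float(np.median(hr)),
        "hr_std": float(hr.std()),
        "hr_max": float(hr.max()),
        "hr_min": float(hr.min()),
    }


# --------------------------------------------------------------------------
# tables


def time_domain_features(segmentation: CycleSegmentation) -> pd.DataFrame:
    """Per-cycle durations (s) of S1, S2, systole, diastole and the cycle,
    with mean/sd summary rows appended (index ``mean`` / ``sd``)."""
    if segmentation.n_cycles == 0:
        raise ValueError("empty segmentation")
    rows = []
    for k, c in enumerate(segmentation.cycles):
        rows.append(
            {
                "cycle": k,
                "s1_duration": c.s1.duration_s,
                "s2_duration": c.s2.duration_s,
                "systolic_duration": c.systole.duration_s,
                "diastolic_duration": c.diastole.duration_s,
                "cycle_duration": c.duration_s,
            }
        )
    df = pd.DataFrame(rows).set_index("cycle")
    summary = pd.DataFrame(
        {col: [df[col].mean(), df[col].std(ddof=1)] for col in df.columns},
        index=["mean", "sd"],
    )
    return pd.concat([df, summary])


def extract_all(
    recording: AudioRecording, segmentation: CycleSegmentation
) -> pd.DataFrame:
    """One feature row per segment per cycle, in deterministic column order.

    Segments too short for a given analysis contribute NaN for those
    features rather than aborting the table.
    """
    rows = []
    for k, c in enumerate(segmentation.cycles):
        for iv in c.intervals():
            row: dict[str, object] = {
                "cycle": k,
                "state": iv.state.value,
                "duration": iv.duration_s,
            }
            amp = amplitude_features(recording, iv)
            row.update({key: amp[key] for key in _AMP_KEYS})
            row.update(stat_features(recording, iv))
            try:
                row.update(f0_features(recording, iv))
                row.update(quality_features(recording, iv))
                row.update(hr_ratio_features(recording, iv))
            except IntervalTooShortError:
                row.update({key: float("nan")
                            for key in _F0_KEYS + _QUALITY_KEYS + _HR_KEYS})
            rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def summarize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample sd of every feature per state, NaN sentinels excluded.

    States appear in cycle order (S1, systole, S2, diastole); columns are
    ``<feature>_mean`` / ``<feature>_sd``.
    """
    order = ["S1", "systole", "S2", "diastole"]
    numeric = [c for c in table.columns if c not in ("cycle", "state")]
    out_rows = []
    for state in order:
        sub = table[table["state"] == state]
        if sub.empty:
            continue
        row: dict[str, object] = {"state": state}
        for col in numeric:
            vals = sub[col].dropna()
            row[f"{col}_mean"] = vals.mean() if len(vals) else float("nan")
            row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else float("nan")
        out_rows.append(row)
    return pd.DataFrame(out_rows).set_index("state")
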