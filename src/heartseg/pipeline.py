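"""End-to-end orchestration, heart-rate estimation, and device cross-validation.

``run_pipeline`` chains the whole tool: read audio -> standardize ->
band-pass -> Shannon envelope -> S1/S2 detection -> outlier filtering ->
boundary localization -> cycle labels -> edge trim -> feature table ->
heart rate, naming the failing stage on any error. ``compare_with_reference``
implements the paired t-test agreement check against an external
heart-rate device (e.g. a fingertip pulse oximeter).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from ._version import __version__
from .audio_io import (
    AudioRecording,
    CycleSegmentation,
    read_audio,
    write_label_track,
)
from .errors import InsufficientCyclesError, PipelineStageError, ValidationInputError
from .features import extract_all, summarize_features
from .preprocess import bandpass, shannon_envelope, standardize, trim_partial_cycles
from .segmentation import SegmenterParams, segment_envelope

__all__ = [
    "estimate_heart_rate",
    "compare_with_reference",
    "run_pipeline",
    "segment_recording",
    "PipelineResult",
    "HRValidationResult",
]


def estimate_heart_rate(segmentation: CycleSegmentation) -> int:
    """Heart rate in bpm: 60 / median cycle duration, rounded half away
    from zero. The median is robust to a single missed or split cycle."""
    if segmentation.n_cycles < 2:
        raise InsufficientCyclesError(
            f"heart-rate estimate needs >= 2 cycles, got {segmentation.n_cycles}"
        )
    med = float(np.median([c.duration_s for c in segmentation.cycles]))
    hr = 60.0 / med
    return int(math.floor(hr + 0.5)) if hr >= 0 else -int(math.floor(-hr + 0.5))


@dataclass(frozen=True)
class HRValidationResult:
    """Paired agreement between two per-subject heart-rate columns."""

    per_subject: tuple[tuple[str, float, float], ...]
    mean_est: float
    sd_est: float
    mean_ref: float
    sd_ref: float
    t_statistic: float
    p_value: float
    significant_at_005: bool

    def summary_row(self) -> str:
        """Formatted like a "Mean (sd)" table row."""
        return (
            f"{self.mean_est:.2f} ({self.sd_est:.2f})\t"
            f"{self.mean_ref:.2f} ({self.sd_ref:.2f})"
        )


def compare_with_reference(
    estimates: list[tuple[str, float]] | pd.DataFrame,
    reference: list[tuple[str, float]] | pd.DataFrame,
) -> HRValidationResult:
    """Two-sided paired t-test of estimated vs reference heart rates.

    Inputs are (subject_id, hr_bpm) pairs (or DataFrames with columns
    ``subject_id``/``hr_bpm``); subjects are matched by id and must match
    exactly. With identical columns the statistic is t = 0, p = 1.
    """
    est = _as_pairs(estimates)
    ref = _as_pairs(reference)
    if set(est) != set(ref):
        raise ValidationInputError(
            f"subject ids do not match: {sorted(set(est) ^ set(ref))}"
        )
    ids = sorted(est)
    if len(ids) < 2:
        raise ValidationInputError("paired t-test needs >= 2 subjects")
    a = np.array([est[i] for i in ids], dtype=float)
    b = np.array([ref[i] for i in ids], dtype=float)
    diff = a - b
    if np.all(diff == 0):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = spstats.ttest_rel(a, b)
        t_stat, p_val = float(t_stat), float(p_val)
    return HRValidationResult(
        per_subject=tuple((i, float(est[i]), float(ref[i])) for i in ids),
        mean_est=float(a.mean()),
        sd_est=float(a.std(ddof=1)),
        mean_ref=float(b.mean()),
        sd_ref=float(b.std(ddof=1)),
        t_statistic=t_stat,
        p_value=p_val,
        significant_at_005=bool(p_val < 0.05),
    )


def _as_pairs(obj) -> dict[str, float]:
    if isinstance(obj, pd.DataFrame):
        return dict(zip(obj["subject_id"].astype(str), obj["hr_bpm"].astype(float)))
    return {str(i): float(v) for i, v in obj}


@dataclass(frozen=True)
class PipelineResult:
    segmentation: CycleSegmentation
    features: pd.DataFrame
    heart_rate_bpm: int
    recording: AudioRecording


def segment_recording(
    recording: AudioRecording, params: SegmenterParams | None = None
) -> tuple[AudioRecording, CycleSegmentation]:
    """Condition a raw recording and segment it; returns the standardized,
    trimmed audio together with the (shifted) labels, so the first S1
    starts at time 0."""
    params = params or SegmenterParams()
    std = standardize(recording)
    filtered = bandpass(std)
    env = shannon_envelope(filtered)
    seg = segment_envelope(env, params)
    return trim_partial_cycles(std, seg)


def run_pipeline(
    path: str | os.PathLike | AudioRecording,
    params: SegmenterParams | None = None,
    outdir: str | os.PathLike | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Audio file (or recording) -> labels + feature table + heart rate.

    With ``outdir`` set, writes ``labels.txt`` (Audacity label track),
    ``features.csv``, ``summary.csv`` and ``manifest.json`` (parameters,
    seed, versions) there. Any stage failure raises
    :class:`PipelineStageError` naming the stage.
    """
    params = params or SegmenterParams()

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    if isinstance(path, AudioRecording):
        rec = path
    else:
        rec = _stage("read_audio", read_audio, path)
    std = _stage("standardize", standardize, rec)
    filtered = _stage("bandpass", bandpass, std)
    env = _stage("envelope", shannon_envelope, filtered)
    seg = _stage("segment", segment_envelope, env, params)
    trimmed, seg = _stage("trim", trim_partial_cycles, std, seg)
    table = _stage("features", extract_all, trimmed, seg)
    hr = _stage("heart_rate", estimate_heart_rate, seg)

    if outdir is not None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        write_label_track(seg, os.path.join(outdir, "labels.txt"))
        table.to_csv(os.path.join(outdir, "features.csv"), index=False)
        summarize_features(table).to_csv(os.path.join(outdir, "summary.csv"))
        manifest = {
            "params": asdict(params),
            "seed": seed,
            "heart_rate_bpm": hr,
            "n_cycles": seg.n_cycles,
            "versions": {
                "heartseg": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return PipelineResult(seg, table, hr, trimmed)
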