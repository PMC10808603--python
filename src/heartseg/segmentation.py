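"""S1/S2 detection and four-state cardiac-cycle labeling.

The algorithm runs on the Shannon-energy envelope of a standardized,
band-passed PCG:

1. candidate peaks above a relative threshold are collected;
2. the quasi-periodic dominant train (the S1 anchors) is selected as the
   candidate subset with the most regular inter-peak intervals inside the
   plausible heart-rate band;
3. for every adjacent S1 pair the highest interior envelope maximum is the
   S2 candidate; candidates whose height or S1->S2 lag deviates wildly from
   the rest are rejected (median +/- k * scaled MAD);
4. burst boundaries are localized by walking the envelope away from each
   peak until it crosses a fraction of the peak height or bottoms out in a
   valley, whichever comes first;
5. cycles are labeled: systole = S1 onset -> S2 onset, diastole = S2 onset
   -> next S1 onset, with the bursts embedded.

If the chosen anchor train turns out to make "systole" the longer phase,
the roles of the two trains are swapped — physiological systole is the
shorter fraction of the cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .audio_io import (
    CardiacCycle,
    CycleSegmentation,
    SegmentInterval,
    SegmentState,
    us_to_seconds,
    seconds_to_us,
)
from .errors import (
    DegenerateSegmentationError,
    NoPeaksError,
    SequencingError,
)
from .preprocess import Envelope

__all__ = [
    "PeakEvent",
    "SegmenterParams",
    "detect_s1_peaks",
    "detect_s2_peaks",
    "filter_s2_outliers",
    "locate_boundaries",
    "build_cycle_labels",
    "validate_physiology",
    "segment_envelope",
    "PhysiologyReport",
    "CyclePhysiology",
]

logger = logging.getLogger(__name__)

_MAD_SCALE = 1.4826  # scaled MAD approximates a standard deviation
# Tolerance floors for the outlier rule: deviations at or below the
# envelope's own resolution (one 10 ms frame hop for lags) or within 1% of
# the median height are measurement noise, not outliers — without a floor a
# tight candidate set (MAD -> 0) would be mass-deleted.
_LAG_TOL_FLOOR_S = 0.010
_HEIGHT_TOL_FLOOR_FRAC = 0.01
# Fraction of the S1->S1 gap excluded around each anchor when searching for
# the interior (S2) maximum, so the anchors' own lobes are never picked.
_S2_GUARD_FRACTION = 0.15


@dataclass(frozen=True)
class PeakEvent:
    """An envelope peak: frame-center time, envelope height, S1/S2 role."""

    time_s: float
    height: float
    kind: SegmentState
    lag_s: float | None = None  # S1->S2 lag, set on S2 candidates

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("peak height must be positive")


@dataclass(frozen=True)
class SegmenterParams:
    """Tunable thresholds of the segmenter.

    min_hr_bpm / max_hr_bpm
        Plausible heart-rate band; bounds both the candidate-peak spacing
        and the cycle-period search.
    peak_rel_threshold
        Candidate peaks must exceed this fraction of the envelope maximum.
    boundary_fraction
        Burst edges sit where the envelope falls to this fraction of the
        peak height (or at the nearest valley, whichever comes first).
    s2_outlier_k
        Robust-deviation multiplier for S2 candidate rejection.
    valley_depth_fraction
        A valley only terminates the boundary walk when the envelope there
        has dropped below this fraction of the peak height; shallower dips
        (e.g. the Shannon-energy depression at the center of a full-scale
        burst) are walked through.
    """

    min_hr_bpm: float = 40.0
    max_hr_bpm: float = 200.0
    peak_rel_threshold: float = 0.2
    boundary_fraction: float = 0.1
    s2_outlier_k: float = 3.0
    valley_depth_fraction: float = 0.5

    def __post_init__(self):
        if not 0 < self.min_hr_bpm < self.max_hr_bpm:
            raise ValueError("need 0 < min_hr_bpm < max_hr_bpm")
        if not 0 < self.boundary_fraction < 1:
            raise ValueError("boundary_fraction must be in (0, 1)")
        if not 0 < self.peak_rel_threshold < 1:
            raise ValueError("peak_rel_threshold must be in (0, 1)")
        if self.s2_outlier_k <= 0:
            raise ValueError("s2_outlier_k must be positive")
        if not 0 < self.valley_depth_fraction <= 1:
            raise ValueError("valley_depth_fraction must be in (0, 1]")

    @property
    def min_period_s(self) -> float:
        return 60.0 / self.max_hr_bpm

    @property
    def max_period_s(self) -> float:
        return 60.0 / self.min_hr_bpm


# --------------------------------------------------------------------------
# S1 anchor train


def detect_s1_peaks(envelope: Envelope, params: SegmenterParams | None = None) -> list[PeakEvent]:
    """Locate the quasi-periodic S1 peak train on the envelope.

    Candidates are local maxima above ``peak_rel_threshold * max(envelope)``
    separated by at least one minimum cardiac period. Among period
    hypotheses drawn from the envelope autocorrelation, the candidate
    subset with the smallest coefficient of variation of inter-peak
    intervals (within the heart-rate band) is returned.
    """
    params = params or SegmenterParams()
    env = envelope.values
    if env.size == 0:
        raise NoPeaksError("empty envelope")
    peak_max = env.max()
    if peak_max <= 0:
        raise NoPeaksError("envelope is identically zero (silence?)")
    min_dist = max(1, int(round(params.min_period_s / envelope.frame_hop_s)))
    idx, _ = sps.find_peaks(env, height=params.peak_rel_threshold * peak_max,
                            distance=min_dist)
    if idx.size == 0:
        raise NoPeaksError("no candidate peaks above threshold")
    if idx.size <= 2:
        return [
            PeakEvent(envelope.time_of(i), float(env[i]), SegmentState.S1)
            for i in idx
        ]

    periods = _period_hypotheses(envelope, params)
    hop = envelope.frame_hop_s
    cand_span = (idx[-1] - idx[0]) * hop
    trains = []
    for period_s in periods:
        train = _build_train(idx, env, hop, period_s)
        if train.size < 2:
            continue
        gaps = np.diff(train) * hop
        mean_gap = float(gaps.mean())
        if not (params.min_period_s <= mean_gap <= params.max_period_s):
            continue
        cv = float(gaps.std() / mean_gap) if mean_gap > 0 else math.inf
        coverage = (train[-1] - train[0]) * hop / cand_span if cand_span > 0 else 1.0
        trains.append((train, cv, coverage, mean_gap))
    best_train = _select_train(trains)
    if best_train is None:
        # fall back to the raw candidate list (already spaced >= min period)
        best_train = idx
    return [
        PeakEvent(_burst_center_time(env, i, envelope), float(env[i]),
                  SegmentState.S1)
        for i in best_train
    ]


def _burst_center_time(env: np.ndarray, j: int, envelope: Envelope) -> float:
    """Envelope-mass centroid of the burst region around frame ``j``.

    The raw argmax is an unstable burst-center estimate: a flat-topped
    burst lets it wander across the plateau with noise, and a loud burst's
    Shannon-energy dip splits it across two humps. The centroid of the
    contiguous region above half the local maximum averages over both
    effects.
    """
    level = 0.5 * env[j]
    a = j
    while a > 0 and env[a - 1] >= level:
        a -= 1
    b = j
    while b < env.size - 1 and env[b + 1] >= level:
        b += 1
    w = env[a : b + 1]
    k = float(np.dot(np.arange(a, b + 1), w) / w.sum())
    return envelope.time_of(k)


def _select_train(
    trains: list[tuple[np.ndarray, float, float, float]]
) -> np.ndarray | None:
    """Pick the S1 train among (train, cv, coverage, mean_gap) candidates.

    Regular trains that span the candidate set are admissible; among them
    the one with the smallest mean gap wins — a train that skips every
    other beat is just as regular (subsampling a jittered train lowers its
    CV) but runs at a multiple of the fundamental period. Trains locked
    onto a single S1->S2 lag have near-zero coverage and are rejected.
    """
    if not trains:
        return None
    min_cv = min(t[1] for t in trains)
    admissible = [
        t for t in trains if t[2] >= 0.8 and t[1] <= max(0.08, 2.0 * min_cv)
    ]
    if admissible:
        return min(admissible, key=lambda t: t[3])[0]
    # nothing both regular and covering: fall back to best regularity+coverage
    return min(trains, key=lambda t: t[1] + (1.0 - t[2]))[0]


def _period_hypotheses(envelope: Envelope, params: SegmenterParams) -> list[float]:
    """Cycle-period candidates from the envelope autocorrelation (top 3)."""
    env = envelope.values - envelope.values.mean()
    hop = envelope.frame_hop_s
    lo = max(1, int(round(params.min_period_s / hop)))
    hi = min(env.size - 1, int(round(params.max_period_s / hop)))
    if hi <= lo:
        return [min(params.max_period_s, max(params.min_period_s, 0.8))]
    ac = sps.correlate(env, env, mode="full", method="auto")[env.size - 1 :]
    band = ac[lo : hi + 1]
    pk, _ = sps.find_peaks(band)
    if pk.size == 0:
        best = [int(np.argmax(band))]
    else:
        best = list(pk[np.argsort(band[pk])[::-1][:3]])
    return [(lo + b) * hop for b in best]


def _build_train(
    idx: np.ndarray, env: np.ndarray, hop_s: float, period_s: float
) -> np.ndarray:
    """Greedy walk from the tallest candidate at the hypothesized period.

    From each accepted peak, the next anchor is the tallest candidate in a
    window [0.55, 1.45] periods ahead (same backward); the window excludes
    the intra-cycle S2 of the current beat but spans the next S1 even under
    cycle-length jitter.
    """
    times = idx * hop_s
    seed_pos = int(np.argmax(env[idx]))
    train = [seed_pos]
    # forward
    cur = seed_pos
    while True:
        lo_t = times[cur] + 0.55 * period_s
        hi_t = times[cur] + 1.45 * period_s
        cand = np.where((times > lo_t) & (times <= hi_t))[0]
        if cand.size == 0:
            break
        nxt = cand[np.argmax(env[idx[cand]])]
        train.append(nxt)
        cur = nxt
    # backward
    cur = seed_pos
    while True:
        lo_t = times[cur] - 1.45 * period_s
        hi_t = times[cur] - 0.55 * period_s
        cand = np.where((times >= lo_t) & (times < hi_t))[0]
        if cand.size == 0:
            break
        prv = cand[np.argmax(env[idx[cand]])]
        train.append(prv)
        cur = prv
    return idx[np.sort(np.array(train))]


# --------------------------------------------------------------------------
# S2 candidates


def detect_s2_peaks(
    envelope: Envelope,
    s1_peaks: list[PeakEvent],
    params: SegmenterParams | None = None,
) -> list[PeakEvent | None]:
    """The highest interior envelope maximum between each adjacent S1 pair.

    Returns one entry per S1 gap, aligned with the gaps; a gap with no
    interior maximum (e.g. silent interior) yields ``None`` as a flagged
    missing-S2 placeholder. A guard zone around each S1 excludes the
    anchors' own lobes from the search.
    """
    params = params or SegmenterParams()
    if len(s1_peaks) < 2:
        raise NoPeaksError("need >= 2 S1 peaks to search for S2")
    env = envelope.values
    out: list[PeakEvent | None] = []
    for a, b in zip(s1_peaks[:-1], s1_peaks[1:]):
        gap = b.time_s - a.time_s
        guard = _S2_GUARD_FRACTION * gap
        i0 = envelope.index_of(a.time_s + guard)
        i1 = envelope.index_of(b.time_s - guard)
        if i1 - i0 < 3:
            out.append(None)
            continue
        seg = env[i0 : i1 + 1]
        pk, _ = sps.find_peaks(seg)
        if pk.size == 0 or seg[pk].max() <= 0:
            out.append(None)
            continue
        j = i0 + pk[np.argmax(seg[pk])]
        t = _burst_center_time(env, j, envelope)
        out.append(
            PeakEvent(t, float(env[j]), SegmentState.S2, lag_s=t - a.time_s)
        )
    return out


def filter_s2_outliers(
    s2_peaks: list[PeakEvent | None], params: SegmenterParams | None = None
) -> list[PeakEvent | None]:
    """Reject S2 candidates far from the consensus height or S1->S2 lag.

    A candidate is removed (replaced by ``None``) when its height or lag
    deviates from the median by more than ``s2_outlier_k`` scaled-MAD units
    (MAD x 1.4826). With fewer than 3 candidates the rule is ill-posed and
    the list passes through unchanged (with a warning). Raises
    :class:`DegenerateSegmentationError` if nothing survives.
    """
    params = params or SegmenterParams()
    present = [p for p in s2_peaks if p is not None]
    if len(present) < 3:
        if present:
            logger.warning(
                "only %d S2 candidates; outlier rule needs >= 3, passing through",
                len(present),
            )
        return list(s2_peaks)
    heights = np.array([p.height for p in present])
    lags = np.array([p.lag_s if p.lag_s is not None else np.nan for p in present])
    keep_h = _mad_keep(heights, params.s2_outlier_k,
                       floor=_HEIGHT_TOL_FLOOR_FRAC * float(np.median(heights)))
    keep_l = _mad_keep(lags, params.s2_outlier_k, floor=_LAG_TOL_FLOOR_S)
    keep = {id(p) for p, kh, kl in zip(present, keep_h, keep_l) if kh and kl}
    out: list[PeakEvent | None] = [
        p if (p is not None and id(p) in keep) else None for p in s2_peaks
    ]
    n_kept = sum(p is not None for p in out)
    if n_kept == 0:
        raise DegenerateSegmentationError("every S2 candidate was filtered out")
    n_dropped = len(present) - n_kept
    if n_dropped:
        logger.info("S2 outlier filter removed %d of %d candidates",
                    n_dropped, len(present))
    return out


def _mad_keep(x: np.ndarray, k: float, floor: float) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    tol = max(k * _MAD_SCALE * mad, floor)
    return np.abs(x - med) <= tol


# --------------------------------------------------------------------------
# boundary localization


def locate_boundaries(
    envelope: Envelope, peak: PeakEvent, params: SegmenterParams | None = None
) -> SegmentInterval:
    """Burst interval around a peak: edges at the fractional-height crossing
    or the nearest envelope valley, whichever lies closer to the peak.

    Crossings are linearly interpolated between frame centers; a peak at
    the envelope edge with no crossing is clipped to the envelope span and
    the returned interval is flagged ``clipped``.
    """
    params = params or SegmenterParams()
    env = envelope.values
    # the peak time may be a plateau center sitting in the Shannon-energy
    # dip of a loud burst; hill-climb to the nearest local maximum so the
    # outward walk starts on top
    p = _hill_climb(env, envelope.index_of(peak.time_s))
    thr = params.boundary_fraction * peak.height

    valley_thr = params.valley_depth_fraction * peak.height
    start_t, start_clip = _walk(env, envelope, p, thr, valley_thr, direction=-1)
    end_t, end_clip = _walk(env, envelope, p, thr, valley_thr, direction=+1)
    # keep the peak strictly inside the interval
    start_t = min(start_t, peak.time_s - 1e-6)
    end_t = max(end_t, peak.time_s + 1e-6)
    start_t = max(0.0, start_t)
    return SegmentInterval(
        start_s=us_to_seconds(seconds_to_us(start_t)),
        end_s=us_to_seconds(seconds_to_us(end_t)),
        state=peak.kind,
        clipped=start_clip or end_clip,
    )


def _hill_climb(env: np.ndarray, p: int) -> int:
    """Greedy ascent to the nearest local envelope maximum."""
    while True:
        left = env[p - 1] if p > 0 else -np.inf
        right = env[p + 1] if p < env.size - 1 else -np.inf
        if left <= env[p] and right <= env[p]:
            return p
        p = p - 1 if left > right else p + 1


def _walk(
    env: np.ndarray,
    envelope: Envelope,
    p: int,
    thr: float,
    valley_thr: float,
    direction: int,
) -> tuple[float, bool]:
    """Walk from frame ``p`` until the envelope crosses ``thr`` or bottoms
    out in a valley deeper than ``valley_thr``.

    Valley termination carries a hysteresis: the envelope must rise at
    least 10% of the peak height above the running minimum before the
    minimum counts as a valley — a one-frame noise up-tick does not end a
    burst. Shallow dips (above ``valley_thr``) are walked through, and if
    the envelope climbs back to the peak's own height — a neighboring
    burst — the boundary falls at the deepest frame seen."""
    hysteresis = 0.1 * env[p]
    i = p
    min_i = p
    while True:
        j = i + direction
        if j < 0 or j >= env.size:
            return envelope.time_of(i), True  # clipped at envelope edge
        if env[j] <= thr:
            # linear interpolation of the crossing between frames i and j
            if env[i] == env[j]:
                frac = 0.0
            else:
                frac = (env[i] - thr) / (env[i] - env[j])
            return envelope.time_of(i + direction * frac), False
        if (
            i != p
            and env[min_i] <= valley_thr
            and env[j] - env[min_i] > hysteresis
        ):
            return envelope.time_of(min_i), False  # confirmed valley
        if env[j] >= env[p] and i != p and env[min_i] <= valley_thr:
            # rose back to peak height after a deep dip: neighboring burst
            return envelope.time_of(min_i), False
        i = j
        if env[i] < env[min_i]:
            min_i = i


# --------------------------------------------------------------------------
# cycle labeling


def build_cycle_labels(
    s1_intervals: list[SegmentInterval],
    s2_intervals: list[SegmentInterval | None],
) -> CycleSegmentation:
    """Assemble four-state cycles from located S1 and S2 bursts.

    Cycle k spans S1_k onset -> S1_{k+1} onset, with systole ending (and
    diastole starting) at the S2 onset. ``s2_intervals`` is aligned with
    the S1 gaps; a ``None`` entry (missing/filtered S2) drops that cycle.
    Burst ends overrunning the next phase boundary are clamped (flagged).
    S2 onsets must fall strictly between their flanking S1 onsets, else a
    :class:`SequencingError` names the offending cycle.
    """
    if len(s1_intervals) < 2:
        raise SequencingError("need >= 2 S1 intervals to close a cycle")
    if len(s2_intervals) != len(s1_intervals) - 1:
        raise SequencingError(
            f"expected {len(s1_intervals) - 1} S2 slots, got {len(s2_intervals)}"
        )
    cycles: list[CardiacCycle] = []
    dropped = 0
    for k, (s1a, s1b, s2) in enumerate(
        zip(s1_intervals[:-1], s1_intervals[1:], s2_intervals)
    ):
        if s1b.start_us <= s1a.start_us:
            raise SequencingError(f"S1 onsets not increasing at cycle {k}", k)
        if s2 is None:
            dropped += 1
            continue
        if not (s1a.start_us < s2.start_us < s1b.start_us):
            raise SequencingError(
                f"cycle {k}: S2 onset {s2.start_s:.6f} not strictly between "
                f"S1 onsets {s1a.start_s:.6f} and {s1b.start_s:.6f}", k
            )
        s1 = s1a
        if s1.end_us > s2.start_us:  # clamp S1 into systole
            s1 = SegmentInterval(s1.start_s, s2.start_s, SegmentState.S1, clipped=True)
        if s1.end_us >= s2.start_us and s1.end_us != s2.start_us:
            raise SequencingError(f"cycle {k}: S1 overruns the S2 onset", k)
        s2c = s2
        if s2c.end_us > s1b.start_us:  # clamp S2 into diastole
            s2c = SegmentInterval(s2c.start_s, s1b.start_s, SegmentState.S2,
                                  clipped=True)
        systole = SegmentInterval(s1.start_s, s2c.start_s, SegmentState.SYSTOLE)
        diastole = SegmentInterval(s2c.start_s, s1b.start_s, SegmentState.DIASTOLE)
        cycles.append(CardiacCycle(s1, systole, s2c, diastole))
    if dropped:
        logger.info("dropped %d cycle(s) with missing S2", dropped)
    return CycleSegmentation(tuple(cycles))


# --------------------------------------------------------------------------
# physiological sanity report


@dataclass(frozen=True)
class CyclePhysiology:
    index: int
    cycle_duration_s: float
    rate_in_band: bool
    s2_within_flanks: bool


@dataclass(frozen=True)
class PhysiologyReport:
    """Read-only report of the identification rules on a segmentation:
    S1 bursts last at least as long as S2 on average, every S2 falls
    strictly between its flanking S1 onsets, and cycle durations imply a
    plausible heart rate."""

    s1_duration_ge_s2: bool
    mean_s1_duration_s: float
    mean_s2_duration_s: float
    per_cycle: tuple[CyclePhysiology, ...] = field(default_factory=tuple)

    @property
    def all_pass(self) -> bool:
        return self.s1_duration_ge_s2 and all(
            c.rate_in_band and c.s2_within_flanks for c in self.per_cycle
        )


def validate_physiology(
    segmentation: CycleSegmentation, params: SegmenterParams | None = None
) -> PhysiologyReport:
    """Check the segmentation against the three identification rules."""
    params = params or SegmenterParams()
    cycles = segmentation.cycles
    s1_durs = [c.s1.duration_s for c in cycles]
    s2_durs = [c.s2.duration_s for c in cycles]
    mean_s1 = float(np.mean(s1_durs)) if s1_durs else float("nan")
    mean_s2 = float(np.mean(s2_durs)) if s2_durs else float("nan")
    per_cycle = []
    for k, c in enumerate(cycles):
        dur = c.duration_s
        in_band = params.min_period_s <= dur <= params.max_period_s
        next_s1_start = (
            cycles[k + 1].s1.start_us if k + 1 < len(cycles) else c.diastole.end_us
        )
        s2_ok = c.s1.start_us < c.s2.start_us < next_s1_start
        per_cycle.append(CyclePhysiology(k, dur, in_band, s2_ok))
    return PhysiologyReport(
        s1_duration_ge_s2=(mean_s1 >= mean_s2) if cycles else True,
        mean_s1_duration_s=mean_s1,
        mean_s2_duration_s=mean_s2,
        per_cycle=tuple(per_cycle),
    )


# --------------------------------------------------------------------------
# envelope -> labels orchestration


def segment_envelope(
    envelope: Envelope, params: SegmenterParams | None = None
) -> CycleSegmentation:
    """Full envelope-to-labels chain: S1 train, interior S2 search, role
    swap if "systole" came out as the longer phase, outlier filtering,
    boundary localization, cycle assembly."""
    params = params or SegmenterParams()
    s1 = detect_s1_peaks(envelope, params)
    if len(s1) < 2:
        raise DegenerateSegmentationError(
            f"only {len(s1)} S1 peak(s); cannot close a cycle"
        )
    s2 = detect_s2_peaks(envelope, s1, params)

    frac = _median_systolic_fraction(s1, s2)
    if frac is not None and frac > 0.5:
        swapped = _swap_roles(envelope, s1, s2, params)
        if swapped is not None:
            s1, s2 = swapped
    elif frac is not None and frac == 0.5:
        # tie: the taller train is S1
        h1 = float(np.median([p.height for p in s1]))
        h2 = float(np.median([p.height for p in s2 if p is not None]))
        if h2 > h1:
            swapped = _swap_roles(envelope, s1, s2, params)
            if swapped is not None:
                s1, s2 = swapped

    s2 = filter_s2_outliers(s2, params)
    s1_iv = [locate_boundaries(envelope, p, params) for p in s1]
    s2_iv = [
        locate_boundaries(envelope, p, params) if p is not None else None
        for p in s2
    ]
    seg = build_cycle_labels(s1_iv, s2_iv)
    logger.info("segmented %d cycle(s) with params %s", seg.n_cycles, params)
    return seg


def _median_systolic_fraction(
    s1: list[PeakEvent], s2: list[PeakEvent | None]
) -> float | None:
    fracs = []
    for a, b, p in zip(s1[:-1], s1[1:], s2):
        if p is not None:
            fracs.append((p.time_s - a.time_s) / (b.time_s - a.time_s))
    return float(np.median(fracs)) if fracs else None


def _swap_roles(
    envelope: Envelope,
    s1: list[PeakEvent],
    s2: list[PeakEvent | None],
    params: SegmenterParams,
) -> tuple[list[PeakEvent], list[PeakEvent | None]] | None:
    """Re-anchor on the interior train (the putative S2s become S1s)."""
    new_s1 = [
        PeakEvent(p.time_s, p.height, SegmentState.S1)
        for p in s2
        if p is not None
    ]
    if len(new_s1) < 2:
        return None
    new_s2 = detect_s2_peaks(envelope, new_s1, params)
    logger.info("swapped S1/S2 roles: systolic fraction exceeded 1/2")
    return new_s1, new_s2
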