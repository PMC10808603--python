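"""Feature battery vs independent brute-force oracles and closed forms."""

import math

import numpy as np
import pytest

from heartseg import (
    AudioRecording,
    SegmentInterval,
    SegmentState,
    amplitude_features,
    extract_all,
    f0_features,
    hr_ratio_features,
    quality_features,
    stat_features,
    summarize_features,
    time_domain_features,
)
from heartseg.errors import IntervalTooShortError
from heartseg.features import DB_FLOOR, FEATURE_COLUMNS

from conftest import make_cycle
from heartseg.audio_io import CycleSegmentation


def _rec(x, fs=1000):
    return AudioRecording(np.asarray(x, dtype=float), fs)


def _iv(rec):
    return SegmentInterval(0.0, rec.duration_s, SegmentState.S1)


# --------------------------------------------------------------------------
# independent brute-force oracles (plain Python loops, no numpy vector ops)


def _brute_stats(xs):
    n = len(xs)
    mean = sum(xs) / n
    absomean = sum(abs(v) for v in xs) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in xs) / n)
    rms = math.sqrt(sum(v * v for v in xs) / n)
    xmax, xmin = max(xs), min(xs)
    peak = max(abs(v) for v in xs)
    sqrt_mean = sum(math.sqrt(abs(v)) for v in xs) / n
    out = {
        "absomean": absomean,
        "STD": std,
        "max": xmax,
        "min": xmin,
        "peak2valley": xmax - xmin,
        "RMS": rms,
        "shapefactor": rms / absomean,
        "impulsefactor": peak / absomean,
        "marginfactor": peak / sqrt_mean**2,
        "energy": sum(v * v for v in xs),
    }
    if std > 0:
        out["skew"] = sum((v - mean) ** 3 for v in xs) / n / std**3
        out["kurt"] = sum((v - mean) ** 4 for v in xs) / n / std**4
    return out


def _brute_amplitude(xs, fs, frame_s=0.02, hop_s=0.01):
    frame_n, hop_n = int(round(frame_s * fs)), int(round(hop_s * fs))
    levels = []
    start = 0
    while start + frame_n <= len(xs):
        fr = xs[start : start + frame_n]
        rms = math.sqrt(sum(v * v for v in fr) / len(fr))
        levels.append(max(20 * math.log10(rms) if rms > 0 else -1e9, DB_FLOOR))
        start += hop_n
    levels.sort()
    n = len(levels)
    mid = levels[n // 2] if n % 2 else 0.5 * (levels[n // 2 - 1] + levels[n // 2])
    return {
        "maxdb": levels[-1],
        "mindb": levels[0],
        "meandb": sum(levels) / n,
        "middledb": mid,
    }


class TestStatOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 101))
        x = rng.uniform(-1, 1, n)
        got = stat_features(_rec(x), _iv(_rec(x)))
        want = _brute_stats(list(x))
        for key, val in want.items():
            assert got[key] == pytest.approx(val, rel=1e-12), key

    def test_alternating_unit_vector_closed_form(self):
        got = stat_features(_rec([1.0, -1.0, 1.0, -1.0], 4),
                            SegmentInterval(0, 1.0, SegmentState.S1))
        assert got["absomean"] == 1.0
        assert got["STD"] == 1.0
        assert got["RMS"] == 1.0
        assert got["shapefactor"] == 1.0
        assert got["impulsefactor"] == 1.0
        assert got["marginfactor"] == 1.0
        assert got["peak2valley"] == 2.0
        assert got["energy"] == 4.0
        assert got["skew"] == 0.0
        assert got["kurt"] == 1.0

    def test_constant_segment_degenerate_sentinels(self):
        got = stat_features(_rec(np.full(100, 0.4)), _iv(_rec(np.zeros(100))))
        assert got["shapefactor"] == pytest.approx(1.0, rel=1e-12)
        assert got["impulsefactor"] == pytest.approx(1.0, rel=1e-12)
        assert math.isnan(got["skew"])
        assert math.isnan(got["kurt"])

    def test_gaussian_kurtosis_near_three(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(100_000)
        x = x / np.max(np.abs(x))
        got = stat_features(_rec(x, 100_000), _iv(_rec(x, 100_000)))
        assert got["kurt"] == pytest.approx(3.0, abs=0.1)

    def test_zero_mean_std_equals_rms_exactly(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-1, 1, 64)
        x = x - x.mean()
        got = stat_features(_rec(x), _iv(_rec(x)))
        assert got["STD"] == got["RMS"]


class TestAmplitude:
    def test_full_scale_constant_is_zero_db(self):
        rec = _rec(np.ones(1000))
        got = amplitude_features(rec, _iv(rec))
        for key in ("maxdb", "mindb", "meandb", "middledb"):
            assert got[key] == pytest.approx(0.0, abs=1e-12)

    def test_half_scale_constant_is_minus_six_db(self):
        rec = _rec(np.full(1000, 0.5))
        got = amplitude_features(rec, _iv(rec))
        for key in ("maxdb", "mindb", "meandb", "middledb"):
            assert got[key] == pytest.approx(20 * math.log10(0.5), rel=1e-12)

    def test_silence_floored_at_minus_120(self):
        rec = _rec(np.zeros(1000))
        got = amplitude_features(rec, _iv(rec))
        assert got["maxdb"] == got["mindb"] == DB_FLOOR

    def test_short_segment_single_frame_flagged(self):
        rec = _rec(np.full(10, 0.5))  # 10 ms at 1 kHz < 20 ms frame
        got = amplitude_features(rec, _iv(rec))
        assert got["short_segment"]
        assert got["maxdb"] == pytest.approx(20 * math.log10(0.5), rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-1, 1, 100)
        rec = _rec(x)
        got = amplitude_features(rec, _iv(rec))
        want = _brute_amplitude(list(x), 1000)
        for key, val in want.items():
            assert got[key] == pytest.approx(val, rel=1e-12), key


@pytest.fixture(scope="module")
def tone():
    fs = 4000
    t = np.arange(fs) / fs
    return _rec(0.8 * np.sin(2 * np.pi * 100 * t), fs)


@pytest.fixture(scope="module")
def noise():
    rng = np.random.default_rng(0)
    return _rec(0.5 * rng.standard_normal(4000), 4000)


class TestF0AndQuality:
    def test_pure_tone_f0_recovered(self, tone):
        got = f0_features(tone, _iv(tone))
        assert got["mean_f0"] == pytest.approx(100.0, abs=1.0)
        assert got["f0variation"] <= 1.0
        assert got["range_f0"] == got["max_f0"] - got["min_f0"]

    def test_pure_tone_zero_jitter_high_hnr(self, tone):
        got = quality_features(tone, _iv(tone))
        assert got["jitter"] == pytest.approx(0.0, abs=1e-9)
        assert got["HNR"] >= 20.0

    def test_white_noise_unvoiced_sentinels(self, noise):
        got = f0_features(noise, _iv(noise))
        assert all(math.isnan(got[k]) for k in got)

    def test_white_noise_negative_hnr(self, noise):
        got = quality_features(noise, _iv(noise))
        assert math.isnan(got["jitter"])  # no voiced frames
        assert got["HNR"] <= 0.0

    def test_harmonic_ratio_separates_tone_from_noise(self, tone, noise):
        ht = hr_ratio_features(tone, _iv(tone))
        hn = hr_ratio_features(noise, _iv(noise))
        assert ht["hr_max"] >= 0.95
        assert hn["hr_mean"] <= 0.3
        assert 0.0 <= hn["hr_min"] <= hn["hr_max"] <= 1.0

    def test_single_frame_zero_spread(self):
        fs = 4000
        t = np.arange(int(0.045 * fs)) / fs  # one 40 ms frame only
        rec = _rec(0.8 * np.sin(2 * np.pi * 100 * t), fs)
        got = hr_ratio_features(rec, _iv(rec))
        assert got["hr_std"] == 0.0

    def test_interval_too_short(self, tone):
        with pytest.raises(IntervalTooShortError):
            f0_features(tone, SegmentInterval(0.0, 0.01, SegmentState.S1))


class TestTables:
    def test_time_domain_example_cycle(self):
        seg = CycleSegmentation((make_cycle(0, 300_000, 830_000),
                                 make_cycle(830_000, 1_130_000, 1_660_000)))
        df = time_domain_features(seg)
        row = df.loc[0]
        assert row["s1_duration"] == pytest.approx(0.12)
        assert row["systolic_duration"] == pytest.approx(0.30)
        assert row["diastolic_duration"] == pytest.approx(0.53)
        assert row["cycle_duration"] == pytest.approx(0.83)
        # identical cycles -> zero sd
        assert df.loc["sd"].fillna(0).eq(0).all()

    def test_extract_all_row_count_and_columns(self, pcg_72bpm):
        rec, truth = pcg_72bpm
        from heartseg.preprocess import standardize

        std = standardize(rec)
        sub = CycleSegmentation(truth.cycles[:10])
        table = extract_all(std, sub)
        assert list(table.columns) == FEATURE_COLUMNS
        assert len(table) == 40  # 10 cycles x 4 segments

    def test_extract_all_empty_segmentation_header_only(self, pcg_72bpm):
        rec, _ = pcg_72bpm
        table = extract_all(rec, CycleSegmentation())
        assert len(table) == 0
        assert list(table.columns) == FEATURE_COLUMNS

    def test_systole_max_level_dominates_s1(self, pcg_72bpm):
        # S1 is inside systole and holds the systolic peak, so the framed
        # level maxima agree
        rec, truth = pcg_72bpm
        from heartseg.preprocess import standardize

        std = standardize(rec)
        table = extract_all(std, CycleSegmentation(truth.cycles[:6]))
        by_state = table.set_index(["cycle", "state"])
        for k in range(6):
            s1 = by_state.loc[(k, "S1"), "maxdb"]
            sys_ = by_state.loc[(k, "systole"), "maxdb"]
            assert sys_ >= s1 - 1e-12

    def test_db_features_nonpositive_on_standardized_input(self, pcg_72bpm):
        rec, truth = pcg_72bpm
        from heartseg.preprocess import standardize

        std = standardize(rec)
        table = extract_all(std, CycleSegmentation(truth.cycles[:4]))
        assert (table[["maxdb", "mindb", "meandb", "middledb"]] <= 1e-9).all().all()

    def test_summary_layout(self, pcg_72bpm):
        rec, truth = pcg_72bpm
        from heartseg.preprocess import standardize

        table = extract_all(standardize(rec), CycleSegmentation(truth.cycles[:4]))
        summary = summarize_features(table)
        assert list(summary.index) == ["S1", "systole", "S2", "diastole"]
        assert "duration_mean" in summary.columns
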