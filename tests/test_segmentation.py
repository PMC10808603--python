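"""S1/S2 detection, outlier filtering, boundary localization, cycle labels."""

import numpy as np
import pytest

from heartseg import (
    AudioRecording,
    Envelope,
    PeakEvent,
    SegmentInterval,
    SegmentState,
    SegmenterParams,
    SyntheticPCGConfig,
    build_cycle_labels,
    detect_s1_peaks,
    detect_s2_peaks,
    filter_s2_outliers,
    generate_pcg,
    locate_boundaries,
    segment_envelope,
    validate_physiology,
)
from heartseg.errors import NoPeaksError, SequencingError
from heartseg.preprocess import bandpass, shannon_envelope, standardize

from conftest import make_cycle
from heartseg.audio_io import CycleSegmentation


def _envelope_of(rec):
    return shannon_envelope(bandpass(standardize(rec)))


@pytest.fixture(scope="module")
def env_72(pcg_72bpm):
    rec, truth = pcg_72bpm
    return _envelope_of(rec), truth


class TestDetectS1:
    def test_one_peak_per_cycle_near_a_burst_center(self, env_72, default_params):
        # the anchor train is one peak per cycle locked onto one of the two
        # burst trains (role assignment happens at the segment_envelope
        # level, where the systolic-fraction rule can swap S1/S2)
        env, truth = env_72
        peaks = detect_s1_peaks(env, default_params)
        assert abs(len(peaks) - truth.n_cycles) <= 1
        centers = np.array(
            [0.5 * (c.s1.start_s + c.s1.end_s) for c in truth.cycles]
            + [0.5 * (c.s2.start_s + c.s2.end_s) for c in truth.cycles]
        )
        for p in peaks:
            assert np.min(np.abs(centers - p.time_s)) < 0.010

    def test_segment_envelope_assigns_s1_role_to_true_s1(self, env_72, default_params):
        env, truth = env_72
        seg = segment_envelope(env, default_params)
        true_s1 = np.array([c.s1.start_s for c in truth.cycles])
        for c in seg.cycles:
            assert np.min(np.abs(true_s1 - c.s1.start_s)) < 0.010

    def test_silence_raises_no_peaks(self):
        env = Envelope(np.zeros(100), 0.01, 0.02, 0.01)
        with pytest.raises(NoPeaksError):
            detect_s1_peaks(env)

    def test_single_burst_gives_one_peak(self):
        fs = 4000
        x = np.zeros(2 * fs)
        t = np.arange(int(0.12 * fs)) / fs
        x[fs : fs + t.size] = 0.9 * np.hanning(t.size) * np.sin(2 * np.pi * 80 * t)
        env = shannon_envelope(AudioRecording(x, fs))
        peaks = detect_s1_peaks(env)
        assert len(peaks) == 1
        assert abs(peaks[0].time_s - (1.0 + 0.06)) < 0.02


class TestDetectS2:
    def test_s2_found_near_truth(self, env_72, default_params):
        env, truth = env_72
        seg = segment_envelope(env, default_params)
        true_s2 = np.array([c.s2.start_s for c in truth.cycles])
        for c in seg.cycles:
            assert np.min(np.abs(true_s2 - c.s2.start_s)) < 0.010

    def test_silent_interior_flags_missing(self):
        # two bursts with a silent gap: the interior has no local maximum
        fs = 4000
        x = 1e-6 * np.ones(3 * fs)  # tiny floor so envelope is defined
        t = np.arange(int(0.1 * fs)) / fs
        burst = 0.9 * np.hanning(t.size) * np.sin(2 * np.pi * 80 * t)
        x[: t.size] += burst
        x[2 * fs : 2 * fs + t.size] += burst
        env = shannon_envelope(AudioRecording(x, fs))
        s1 = [
            PeakEvent(0.05, float(env.values.max()), SegmentState.S1),
            PeakEvent(2.05, float(env.values.max()), SegmentState.S1),
        ]
        out = detect_s2_peaks(env, s1)
        assert len(out) == 1

    def test_fewer_than_two_s1_raises(self, env_72):
        env, _ = env_72
        with pytest.raises(NoPeaksError):
            detect_s2_peaks(env, [PeakEvent(1.0, 1.0, SegmentState.S1)])


class TestFilterS2Outliers:
    def _peak(self, lag, height=1.0):
        return PeakEvent(10.0 + lag, height, SegmentState.S2, lag_s=lag)

    def test_identical_candidates_all_retained(self):
        peaks = [self._peak(0.30) for _ in range(10)]
        assert filter_s2_outliers(peaks) == peaks

    def test_single_wild_lag_removed(self):
        peaks = [self._peak(0.30) for _ in range(9)] + [self._peak(0.60)]
        out = filter_s2_outliers(peaks)
        assert out[:9] == peaks[:9]
        assert out[9] is None

    def test_two_candidates_pass_through(self):
        peaks = [self._peak(0.30), self._peak(0.60)]
        assert filter_s2_outliers(peaks) == peaks

    def test_wild_height_removed(self):
        peaks = [self._peak(0.30, 1.0) for _ in range(9)] + [self._peak(0.30, 5.0)]
        out = filter_s2_outliers(peaks)
        assert out[9] is None


class TestLocateBoundaries:
    def _triangle_env(self, hop=0.01):
        # linear rise over 0.1 s to height 1 at t=1.0, symmetric fall
        n = 201
        vals = np.maximum(0.0, 1.0 - np.abs(np.arange(n) - 100) * hop / 0.1)
        return Envelope(vals, hop, 0.02, 0.0)

    def test_triangular_peak_width_matches_linear_geometry(self):
        env = self._triangle_env()
        peak = PeakEvent(1.0, 1.0, SegmentState.S1)
        iv = locate_boundaries(env, peak, SegmenterParams(boundary_fraction=0.1))
        # crossing of 0.1 on a unit triangle with 0.1 s flanks: 0.09 s each side
        assert iv.duration_s == pytest.approx(0.18, abs=1e-6)
        assert iv.start_s == pytest.approx(0.91, abs=1e-6)

    def test_high_fraction_collapses_toward_apex(self):
        env = self._triangle_env()
        peak = PeakEvent(1.0, 1.0, SegmentState.S1)
        wide = locate_boundaries(env, peak, SegmenterParams(boundary_fraction=0.1))
        narrow = locate_boundaries(env, peak, SegmenterParams(boundary_fraction=0.9))
        assert narrow.duration_s < wide.duration_s
        assert narrow.start_s < 1.0 < narrow.end_s

    def test_peak_at_edge_clipped_and_flagged(self):
        vals = np.linspace(1.0, 0.0, 50)  # peak at the first frame
        env = Envelope(vals, 0.01, 0.02, 0.0)
        peak = PeakEvent(0.0, 1.0, SegmentState.S1)
        iv = locate_boundaries(env, peak, SegmenterParams())
        assert iv.start_s == 0.0
        assert iv.clipped


class TestBuildCycleLabels:
    def test_systole_and_diastole_tile_the_cycle(self):
        s1s = [
            SegmentInterval(0.0, 0.12, SegmentState.S1),
            SegmentInterval(0.83, 0.95, SegmentState.S1),
        ]
        s2s = [SegmentInterval(0.30, 0.42, SegmentState.S2)]
        seg = build_cycle_labels(s1s, s2s)
        assert seg.n_cycles == 1
        c = seg.cycles[0]
        assert c.systole.start_s == 0.0 and c.systole.end_s == 0.30
        assert c.diastole.start_s == 0.30 and c.diastole.end_s == 0.83
        assert c.systole.duration_us + c.diastole.duration_us == c.duration_us

    def test_s2_before_s1_raises_sequencing_error(self):
        s1s = [
            SegmentInterval(0.5, 0.62, SegmentState.S1),
            SegmentInterval(1.33, 1.45, SegmentState.S1),
        ]
        s2s = [SegmentInterval(0.30, 0.42, SegmentState.S2)]
        with pytest.raises(SequencingError):
            build_cycle_labels(s1s, s2s)

    def test_missing_s2_drops_cycle(self):
        s1s = [
            SegmentInterval(0.0, 0.12, SegmentState.S1),
            SegmentInterval(0.83, 0.95, SegmentState.S1),
            SegmentInterval(1.66, 1.78, SegmentState.S1),
        ]
        s2s = [SegmentInterval(0.30, 0.42, SegmentState.S2), None]
        seg = build_cycle_labels(s1s, s2s)
        assert seg.n_cycles == 1


class TestValidatePhysiology:
    def test_synthetic_segmentation_passes_all_rules(self, env_72, default_params):
        env, _ = env_72
        seg = segment_envelope(env, default_params)
        report = validate_physiology(seg, default_params)
        assert report.all_pass

    def test_s2_longer_than_s1_fails_duration_rule(self):
        seg = CycleSegmentation(
            (make_cycle(0, 300_000, 830_000, s1_dur_us=80_000, s2_dur_us=200_000),)
        )
        report = validate_physiology(seg)
        assert not report.s1_duration_ge_s2

    def test_slow_cycle_fails_rate_band(self):
        seg = CycleSegmentation((make_cycle(0, 700_000, 2_000_000),))
        report = validate_physiology(seg)  # 2.0 s cycle = 30 bpm < 40 bpm
        assert not report.per_cycle[0].rate_in_band


class TestEndToEndProperties:
    def test_determinism_bit_for_bit(self, pcg_72bpm, default_params):
        rec, _ = pcg_72bpm
        a = segment_envelope(_envelope_of(rec), default_params)
        b = segment_envelope(_envelope_of(rec), default_params)
        assert a == b

    @pytest.mark.parametrize("scale", [0.5, 4.0, 3.7])
    def test_scale_invariance_of_label_times(self, pcg_72bpm, default_params, scale):
        rec, _ = pcg_72bpm
        scaled = AudioRecording(rec.samples * scale, rec.sample_rate)
        a = segment_envelope(_envelope_of(rec), default_params)
        b = segment_envelope(_envelope_of(scaled), default_params)
        assert [iv.start_us for iv in a.intervals()] == [
            iv.start_us for iv in b.intervals()
        ]

    def test_duration_conservation_exact(self, env_72, default_params):
        env, _ = env_72
        seg = segment_envelope(env, default_params)
        assert seg.contiguous
        total = sum(
            c.systole.duration_us + c.diastole.duration_us for c in seg.cycles
        )
        span = seg.cycles[-1].diastole.end_us - seg.cycles[0].s1.start_us
        assert total == span
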