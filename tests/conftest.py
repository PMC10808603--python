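import numpy as np
import pytest

from heartseg import (
    CardiacCycle,
    CycleSegmentation,
    SegmentInterval,
    SegmentState,
    SegmenterParams,
    SyntheticPCGConfig,
    generate_pcg,
)


@pytest.fixture(scope="session")
def default_params():
    return SegmenterParams()


@pytest.fixture(scope="session")
def pcg_72bpm():
    """A 20 s synthetic PCG at 72 bpm, SNR 20 dB, with ground truth."""
    cfg = SyntheticPCGConfig(heart_rate_bpm=72.0, duration_s=20.0, snr_db=20.0, seed=1)
    return generate_pcg(cfg)


def make_cycle(start_us: int, s2_onset_us: int, end_us: int,
               s1_dur_us: int = 120_000, s2_dur_us: int = 100_000) -> CardiacCycle:
    """A hand-built cycle from integer-microsecond boundary times."""
    def s(us: int) -> float:
        # divide (not multiply by 1e-6): division by the exactly
        # representable 1e6 is correctly rounded, matching label parsing
        return us / 1e6

    return CardiacCycle(
        s1=SegmentInterval(s(start_us), s(start_us + s1_dur_us), SegmentState.S1),
        systole=SegmentInterval(s(start_us), s(s2_onset_us), SegmentState.SYSTOLE),
        s2=SegmentInterval(s(s2_onset_us), s(s2_onset_us + s2_dur_us),
                           SegmentState.S2),
        diastole=SegmentInterval(s(s2_onset_us), s(end_us), SegmentState.DIASTOLE),
    )


def random_segmentation(rng: np.random.Generator, max_cycles: int = 5) -> CycleSegmentation:
    """A random valid segmentation with all times on the microsecond grid."""
    n = int(rng.integers(1, max_cycles + 1))
    cycles = []
    t = int(rng.integers(0, 2_000_000))
    for _ in range(n):
        cycle_us = int(rng.integers(400_000, 1_400_000))
        s1_dur = int(rng.integers(50_000, cycle_us // 4))
        s2_onset = t + int(rng.integers(s1_dur + 1_000, cycle_us // 2))
        s2_dur = int(rng.integers(40_000, t + cycle_us - s2_onset))
        cycles.append(make_cycle(t, s2_onset, t + cycle_us, s1_dur, s2_dur))
        t += cycle_us
    return CycleSegmentation(tuple(cycles))
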