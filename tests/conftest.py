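"""Shared fixtures: small synthetic series kept cheap enough for CI."""

import numpy as np
import pytest

from lacdqf.seqmodel import TimingSchedule
from lacdqf.synthgen import GroundTruth, generate_series


@pytest.fixture(scope="session")
def paper_schedule() -> TimingSchedule:
    """The in vivo acquisition plan: interleaved, TR 4 s, 300 shots."""
    return TimingSchedule()


@pytest.fixture(scope="session")
def small_schedule() -> TimingSchedule:
    """A short interleaved plan for fast unit tests."""
    return TimingSchedule(n_measurements=60, tau1_max=250.0)


@pytest.fixture(scope="session")
def clean_ground_truth() -> GroundTruth:
    """Noise-free, drift-free, outlier-free generating parameters."""
    return GroundTruth(snr=1e6, drift_hz_per_min=0.0, outlier_rate=0.0)


@pytest.fixture(scope="session")
def clean_series(clean_ground_truth, paper_schedule):
    return generate_series(clean_ground_truth, paper_schedule)


@pytest.fixture(scope="session")
def noisy_small_series(small_schedule):
    gt = GroundTruth(seed=7, outlier_rate=0.0)
    return generate_series(gt, small_schedule)
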