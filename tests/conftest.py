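import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from hrvpc.protocol import build_cohort_from_series
from hrvpc.signal_io import RriSeries
from hrvpc.synthetic_data import GeneratorParams, generate_cohort_series, ipfm_generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rri(rng) -> RriSeries:
    """Gaussian RR series around 900 ms, 300 beats."""
    return RriSeries.from_intervals(900 + 40 * rng.standard_normal(300))


@pytest.fixture(scope="session")
def physio_segment() -> RriSeries:
    """One 5-min physiologic IPFM segment (70 bpm, LF+HF modulation)."""
    return ipfm_generate(GeneratorParams(
        target_HR=70, a_LF=0.03, f_LF=0.1, a_HF=0.03, f_HF=0.25,
        noise_sd=0.02, duration=300, seed=7))


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default-preset 16/42 cohort built once for the statistics, feature
    and benchmark tests (fixed seed)."""
    truth, series = generate_cohort_series(seed=11)
    groups = dict(truth.groupby("subject_id")["group"].first())
    return build_cohort_from_series(series, groups)
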