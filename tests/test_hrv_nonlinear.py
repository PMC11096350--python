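import math

import numpy as np
import pytest

from hrvpc.errors import InsufficientDataError, ValidationError
from hrvpc.hrv_nonlinear import (EmbeddingConfig, apen, cordim,
                                 correlation_sum, dfa, poincare, rqa, sampen)
from hrvpc.hrv_linear import time_domain_metrics
from hrvpc.signal_io import RriSeries
from hrvpc.synthetic_data import GeneratorParams, ipfm_generate
from oracles import (apen_reference, correlation_sum_reference, rqa_reference,
                     sampen_reference)


def _series(rng, n=30, mean=900, sd=40):
    return RriSeries.from_intervals(mean + sd * rng.standard_normal(n))


class TestPoincare:
    def test_constant_series(self):
        m = poincare(RriSeries.from_intervals([1000.0] * 10))
        assert m.SD1 == 0 and m.SD2 == 0
        assert math.isnan(m.SD1_SD2)

    def test_strict_alternation_closed_form(self):
        m = poincare(RriSeries.from_intervals([800.0, 850.0] * 30))
        assert m.SD1 == pytest.approx(math.sqrt(2500 / 2), rel=1e-12)
        assert m.SD2 == pytest.approx(0.0, abs=1e-9)

    def test_sd1_equals_rmssd_over_sqrt2(self, random_rri):
        m = poincare(random_rri)
        rmssd = time_domain_metrics(random_rri).RMSSD
        assert m.SD1 == pytest.approx(rmssd / math.sqrt(2), rel=1e-9)

    def test_time_reversal_invariance(self, random_rri):
        fwd = poincare(random_rri)
        rev = poincare(RriSeries.from_intervals(random_rri.intervals[::-1]))
        assert fwd.SD1 == pytest.approx(rev.SD1, rel=1e-9)
        assert fwd.SD2 == pytest.approx(rev.SD2, rel=1e-9)


class TestRqa:
    def test_periodic_orbit_structure(self):
        pattern = [800.0, 900.0, 1000.0, 1100.0, 1200.0]
        iv = pattern * 40  # period 5, 200 beats
        s = RriSeries.from_intervals(iv)
        m = rqa(s, EmbeddingConfig(m=10, tau=1), r=1.0)  # only exact recurrences
        n_embedded = 200 - 9
        # the offset-190 diagonal has length 1 < lmin, leaving 2 recurrent
        # points off-line, so DET is 100% up to that boundary effect
        assert m.DET == pytest.approx(100.0, abs=0.1)
        assert m.Lmax == n_embedded - 5

    def test_tiny_radius_no_recurrences(self):
        iv = np.arange(1, 31) * 500.0
        with pytest.warns(UserWarning, match="no recurrent"):
            m = rqa(RriSeries.from_intervals(iv), EmbeddingConfig(m=2, tau=1),
                    r=1e-6)
        assert m.REC == 0.0

    def test_brute_force_equivalence(self, rng):
        for _ in range(5):
            s = _series(rng, n=30)
            sd = s.intervals.std()
            r = math.sqrt(3) * sd
            m = rqa(s, EmbeddingConfig(m=3, tau=1), r=r).as_dict()
            ref = rqa_reference(s.intervals, 3, 1, r)
            for key in ref:
                assert m[key] == pytest.approx(ref[key], abs=1e-12), key

    def test_div_lmax_reciprocal(self, physio_segment):
        m = rqa(physio_segment)
        assert m.DIV * m.Lmax == pytest.approx(1.0, rel=1e-12)

    def test_translation_invariance(self, rng):
        s = _series(rng, n=40)
        shifted = RriSeries.from_intervals(s.intervals + 500.0)
        a = rqa(s, EmbeddingConfig(m=3, tau=1)).as_dict()
        b = rqa(shifted, EmbeddingConfig(m=3, tau=1)).as_dict()
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-9), key

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            rqa(RriSeries.from_intervals([1000.0] * 10), EmbeddingConfig(m=10))


class TestDfa:
    def test_white_noise_scaling(self):
        # over boxes 4..16 the standard estimator carries the known
        # small-box bias (exact E[F^2(n)] = sigma^2 (n^2-4)/(15n), LS slope
        # ~0.59); the long-range exponent is unbiased at 0.5
        rng = np.random.default_rng(42)
        s = RriSeries.from_intervals(1000 + 30 * rng.standard_normal(10000))
        a1, a2 = dfa(s)
        assert a1 == pytest.approx(0.586, abs=0.05)
        assert a2 == pytest.approx(0.5, abs=0.05)

    def test_brownian_three_halves(self):
        rng = np.random.default_rng(42)
        steps = rng.standard_normal(10000)
        iv = 100000 + 30 * np.cumsum(steps)  # offset keeps intervals positive
        a1, _ = dfa(RriSeries.from_intervals(iv))
        assert a1 == pytest.approx(1.5, abs=0.08)

    def test_scale_invariance(self, random_rri):
        a = dfa(random_rri)
        b = dfa(RriSeries.from_intervals(random_rri.intervals * 3.7))
        assert a[0] == pytest.approx(b[0], rel=1e-9)
        assert a[1] == pytest.approx(b[1], rel=1e-9)

    def test_constant_series_undefined(self):
        with pytest.raises(ValidationError):
            dfa(RriSeries.from_intervals([1000.0] * 200))


class TestEntropies:
    def test_periodic_sampen_zero(self):
        iv = [700.0, 900.0, 1100.0] * 20
        assert sampen(RriSeries.from_intervals(iv)) == pytest.approx(0.0, abs=1e-12)

    def test_oracle_equivalence(self, rng):
        for _ in range(5):
            s = _series(rng, n=20)
            sd = s.intervals.std()
            r = 0.2 * sd
            assert apen(s) == pytest.approx(
                apen_reference(s.intervals, 2, r), abs=1e-12)
            got = sampen(s)
            want = sampen_reference(s.intervals, 2, r)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_translation_invariance(self, rng):
        s = _series(rng, n=60)
        shifted = RriSeries.from_intervals(s.intervals + 321.0)
        assert apen(s) == pytest.approx(apen(shifted), rel=1e-9)
        assert sampen(s) == pytest.approx(sampen(shifted), rel=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError):
            sampen(RriSeries.from_intervals([1000.0] * 30))


class TestCorrelationSum:
    def test_identical_points_fraction_one(self):
        # 4 identical embedded points: fraction-of-pairs convention gives 1;
        # the 1/(N(N-1)) prefactor with an i<j sum would give 0.5
        s = RriSeries.from_intervals([1000.0] * 5)
        c = correlation_sum(s, m=2, tau=1, r=1.0)
        assert c == 1.0
        n = 4
        printed_convention = sum(
            1 for i in range(n) for j in range(i + 1, n)) / (n * (n - 1))
        assert printed_convention == 0.5

    def test_radius_below_min_distance(self):
        s = RriSeries.from_intervals([500.0, 1000.0, 1500.0, 2000.0, 2500.0])
        assert correlation_sum(s, m=2, tau=1, r=1e-9) == 0.0

    def test_enumeration_oracle(self, rng):
        s = _series(rng, n=10, sd=60)
        sd = s.intervals.std()
        for r in np.geomspace(0.05, 3.0, 20) * sd:
            got = correlation_sum(s, m=3, tau=1, r=float(r))
            want = correlation_sum_reference(s.intervals, 3, 1, float(r))
            assert got == pytest.approx(want, abs=1e-15)

    def test_nonpositive_radius_rejected(self, random_rri):
        with pytest.raises(ValidationError):
            correlation_sum(random_rri, m=2, tau=1, r=0.0)


class TestCorDim:
    def test_constant_series_dimension_zero(self):
        assert cordim(RriSeries.from_intervals([1000.0] * 200)) == 0.0

    def test_clean_sinusoid_is_one_dimensional(self):
        # incommensurate rate so the limit cycle is densely sampled
        rri = ipfm_generate(GeneratorParams(
            target_HR=67.3, a_LF=0.05, a_HF=0, noise_sd=0,
            duration=1200 * 60 / 67.3 + 10, seed=2))
        assert cordim(rri) == pytest.approx(1.0, abs=0.15)

    def test_white_noise_exceeds_limit_cycle(self):
        rng = np.random.default_rng(3)
        noise = RriSeries.from_intervals(900 + 50 * rng.standard_normal(400))
        sine = ipfm_generate(GeneratorParams(
            target_HR=67.3, a_LF=0.05, a_HF=0, noise_sd=0, duration=360, seed=2))
        assert cordim(noise) > cordim(sine)
        assert cordim(noise) > 5.0  # grows toward the embedding bound

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            cordim(RriSeries.from_intervals([1000.0, 900.0] * 40))
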