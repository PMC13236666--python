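"""HRV feature definitions against brute-force oracles and known identities."""

import math

import numpy as np
import pytest

from ecgload.hrv import (
    poincare,
    sample_entropy,
    session_aggregate,
    session_features,
    spectral,
    time_domain,
    windowed_time_domain,
    WindowFeatures,
)
from ecgload.records import RRSeries
from ecgload.synthetic import generate_rr_series
from tests.conftest import clean_spec


def rr_from_ms(intervals_ms):
    beats = np.concatenate(([0.0], np.cumsum(np.asarray(intervals_ms) / 1000.0)))
    return RRSeries.from_beat_times(beats)


class TestTimeDomain:
    def test_three_interval_example(self):
        rmssd, sdnn, mean_hr = time_domain(np.array([800.0, 810.0, 790.0]))
        assert rmssd == pytest.approx(math.sqrt((10**2 + 20**2) / 2), abs=1e-9)
        assert sdnn == pytest.approx(10.0, abs=1e-9)
        assert mean_hr == pytest.approx(75.0, abs=1e-9)

    def test_constant_series(self):
        rmssd, sdnn, _ = time_domain(np.full(20, 950.0))
        assert rmssd == 0.0 and sdnn == 0.0

    def test_time_reversal_symmetry(self, rng):
        x = rng.uniform(700, 900, 50)
        a = time_domain(x)
        b = time_domain(x[::-1])
        assert a[0] == pytest.approx(b[0], abs=1e-9)
        assert a[1] == pytest.approx(b[1], abs=1e-9)

    def test_brute_force_definitions(self, rng):
        x = rng.uniform(600, 1000, 200)
        rmssd, sdnn, mean_hr = time_domain(x)
        # independent element-wise evaluation
        sq = [(x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1)]
        assert rmssd == pytest.approx(math.sqrt(sum(sq) / len(sq)), abs=1e-9)
        mu = sum(x) / len(x)
        assert sdnn == pytest.approx(
            math.sqrt(sum((v - mu) ** 2 for v in x) / (len(x) - 1)), abs=1e-9
        )


class TestSpectral:
    def test_single_lf_tone_concentrates_power(self):
        t = np.arange(0.35, 300.0, 0.8)
        rr_ms = 800.0 + 30.0 * np.sin(2 * np.pi * 0.1 * t)
        rr = RRSeries.from_beat_times(np.concatenate(([0.0], np.cumsum(rr_ms / 1000.0))))
        sf = spectral(rr)
        assert sf.lf_power / (sf.lf_power + sf.hf_power) >= 0.9

    def test_equal_amplitude_tones_near_unit_ratio(self):
        rng = np.random.default_rng(8)
        # interval-domain tones of equal amplitude at the band centres
        n = 500
        t = np.cumsum(np.full(n, 0.5))
        rr_ms = (
            500.0
            + 20.0 * np.sin(2 * np.pi * 0.1 * t)
            + 20.0 * np.sin(2 * np.pi * 0.25 * t + 1.0)
        )
        rr = RRSeries.from_beat_times(np.concatenate(([0.0], np.cumsum(rr_ms / 1000.0))))
        sf = spectral(rr)
        assert 0.8 <= sf.lf_hf <= 1.2

    def test_band_power_bounded_by_total(self, long_rr):
        sf = spectral(long_rr)
        assert sf.lf_power + sf.hf_power <= sf.total_power * (1 + 1e-6)
        assert sf.lf_power >= 0 and sf.hf_power >= 0

    def test_short_span_rejected(self):
        rr = rr_from_ms(np.full(40, 800.0))  # 32 s
        with pytest.raises(ValueError):
            spectral(rr)

    def test_target_recovery_at_session_length(self):
        ests = []
        for seed in range(20):
            rr = generate_rr_series(
                clean_spec(lf_hf_target=1.76, duration_min=5.0, seed=seed)
            )
            ests.append(spectral(rr).lf_hf)
        assert abs(np.mean(ests) - 1.76) / 1.76 <= 0.15


class TestPoincare:
    def test_sd1_equals_rmssd_over_sqrt2(self, rng):
        x = rng.uniform(600, 1000, 300)
        rmssd, _, _ = time_domain(x)
        sd1, _ = poincare(x)
        assert sd1 == pytest.approx(rmssd / math.sqrt(2), abs=1e-9)

    def test_constant_series(self):
        sd1, sd2 = poincare(np.full(10, 800.0))
        assert sd1 == 0.0 and sd2 == 0.0

    def test_direct_formula_on_triple(self):
        x = np.array([800.0, 810.0, 790.0])
        sd1, sd2 = poincare(x)
        # RMS of successive differences / sqrt(2)
        assert sd1 == pytest.approx(math.sqrt((100 + 400) / 2) / math.sqrt(2), abs=1e-9)
        sums = np.array([1610.0, 1600.0])
        assert sd2 == pytest.approx(np.std(sums) / math.sqrt(2), abs=1e-9)

    def test_sd1_below_sd2_for_stationary_series(self, long_rr):
        sd1, sd2 = poincare(long_rr)
        assert sd1 <= sd2


def sampen_oracle(x, m, r):
    """Literal O(N^2) template-counting SampEn for small series."""
    x = list(map(float, x))
    tol = r * float(np.std(x))
    n_tpl = len(x) - m  # same template count at both lengths

    def count(mm):
        tpl = [x[i : i + mm] for i in range(n_tpl)]
        c = 0
        for i in range(len(tpl)):
            for j in range(i + 1, len(tpl)):
                if max(abs(a - b) for a, b in zip(tpl[i], tpl[j])) <= tol:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(150, 800.0)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_alternating_series(self):
        x = np.tile([780.0, 820.0], 60)  # strict period-2 alternation
        assert sample_entropy(x) == pytest.approx(sampen_oracle(x, 2, 0.2), abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_series(self, rng):
        x = rng.uniform(700, 900, 180)
        assert sample_entropy(x) == pytest.approx(sampen_oracle(x, 2, 0.2), abs=1e-12)

    def test_noise_more_entropic_than_sinusoid(self):
        wins = 0
        n = 20
        for seed in range(n):
            g = np.random.default_rng(seed)
            t = np.arange(300)
            sine = 800 + 50 * np.sin(2 * np.pi * 0.05 * t)
            noise = 800 + 50 / math.sqrt(2) * g.standard_normal(300) * math.sqrt(2)
            if sample_entropy(noise) > sample_entropy(sine):
                wins += 1
        assert wins >= int(0.95 * n)


class TestAggregation:
    def test_single_window_equals_aggregate(self):
        w = WindowFeatures(0.0, 60.0, rmssd=40.0, sdnn=55.0, mean_hr=150.0)
        agg = session_aggregate([w])
        assert agg["rmssd"] == 40.0 and agg["sdnn"] == 55.0
        assert agg["mean_hr"] == 150.0

    def test_mean_over_two_windows(self):
        ws = [
            WindowFeatures(0, 60, rmssd=40.0, sdnn=50.0, mean_hr=140.0),
            WindowFeatures(30, 90, rmssd=60.0, sdnn=70.0, mean_hr=160.0),
        ]
        agg = session_aggregate(ws)
        assert agg["rmssd"] == 50.0
        assert agg["sdnn"] == 60.0

    def test_constant_hr_percentile_fallback(self):
        ws = [WindowFeatures(30 * i, 30 * i + 60, 10.0, 10.0, 150.0) for i in range(5)]
        agg = session_aggregate(ws, meta=None)
        assert agg["resting_hr"] == pytest.approx(150.0)
        assert agg["hr_reserve"] == pytest.approx(0.0)

    def test_metadata_supplies_rest_and_max(self, spec):
        ws = [WindowFeatures(0, 60, 10.0, 10.0, 150.0)]
        agg = session_aggregate(ws, meta=spec)
        assert agg["resting_hr"] == spec.resting_hr
        assert agg["hr_reserve"] == pytest.approx(spec.max_hr - spec.resting_hr)

    def test_no_valid_windows_rejected(self):
        with pytest.raises(ValueError):
            session_aggregate([])


def test_stationary_halves_agree():
    """First- vs second-half features differ by < 10% in the median over seeds."""
    rel_diffs = {0: [], 1: [], 2: []}
    for seed in range(9):
        rr = generate_rr_series(clean_spec(duration_min=6.0, seed=100 + seed))
        mid = rr.n_beats // 2
        fa = time_domain(RRSeries.from_beat_times(rr.beat_times[:mid]))
        fb = time_domain(RRSeries.from_beat_times(rr.beat_times[mid:]))
        for i, (va, vb) in enumerate(zip(fa, fb)):
            rel_diffs[i].append(abs(va - vb) / va)
    for diffs in rel_diffs.values():
        assert np.median(diffs) < 0.10


def test_session_features_vector(long_rr, spec):
    feats = session_features(long_rr, spec)
    assert feats.n_windows == len(windowed_time_domain(long_rr))
    assert feats.sd1 == pytest.approx(feats.rmssd / math.sqrt(2), rel=0.05)
    assert feats.lf_hf is not None and feats.lf_hf > 0
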