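"""Conditioning-chain contracts: filters, artifacts, gaps, SNR, normalization."""

import dataclasses
import math

import numpy as np
import pytest

from ecgload.preprocess import (
    ECG_BANDPASS,
    FilterSpec,
    SnrResult,
    bandpass_ecg,
    compute_snr,
    detect_artifacts,
    interpolate_gaps,
    make_windows,
    mitigate_artifacts,
    preprocess_record,
    remove_outliers,
    true_snr,
    zscore,
)
from ecgload.records import EcgRecord
from ecgload.synthetic import NoiseSpec, generate_rr_series, synthesize_ecg
from tests.conftest import clean_spec

FS = 250.0


def tone(freq, duration=20.0, fs=FS, amp=1.0):
    t = np.arange(0, duration, 1.0 / fs)
    return EcgRecord(samples=amp * np.sin(2 * np.pi * freq * t), sampling_rate=fs)


class TestBandpass:
    def test_stopband_tone_attenuated(self):
        rec = tone(0.2)  # wander surrogate, below the 0.5 Hz edge
        out = bandpass_ecg(rec)
        assert np.sqrt(np.mean(out.samples**2)) < 0.05 * np.sqrt(np.mean(rec.samples**2))

    def test_passband_tone_preserved(self):
        rec = tone(10.0)
        out = bandpass_ecg(rec)
        ratio = np.sqrt(np.mean(out.samples**2)) / np.sqrt(np.mean(rec.samples**2))
        assert abs(ratio - 1.0) < 0.05

    def test_wander_removed_from_synthetic_record(self):
        spec = clean_spec(duration_min=2.0)
        rr = generate_rr_series(spec)
        clean = synthesize_ecg(rr, spec)
        wspec = dataclasses.replace(
            spec, noise_profile=NoiseSpec(baseline_wander_amplitude=0.5)
        )
        noisy = synthesize_ecg(rr, wspec)
        n = min(clean.samples.size, noisy.samples.size)

        def sub_halfhz_power(x):
            f = np.fft.rfftfreq(x.size, 1 / FS)
            p = np.abs(np.fft.rfft(x - x.mean())) ** 2
            return p[(f > 0) & (f < 0.5)].sum() / x.size

        filtered = bandpass_ecg(noisy).samples[:n]
        assert sub_halfhz_power(filtered) < 1.1 * sub_halfhz_power(clean.samples[:n]) + 1e-9

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_ecg(tone(10.0), FilterSpec("bandpass", (0.5, 130.0), 4))

    def test_linearity(self):
        rec = tone(7.0)
        a = bandpass_ecg(rec.with_samples(3.7 * rec.samples)).samples
        b = 3.7 * bandpass_ecg(rec).samples
        np.testing.assert_allclose(a, b, atol=1e-9 * np.abs(b).max())

    def test_zero_phase_no_lag(self):
        rec = tone(5.0, duration=10.0)
        out = bandpass_ecg(rec).samples
        xc = np.correlate(rec.samples, out, mode="full")
        lag = int(np.argmax(xc)) - (rec.samples.size - 1)
        assert lag == 0


class TestArtifacts:
    def test_homogeneous_noise_unflagged(self, rng):
        rec = EcgRecord(samples=rng.standard_normal(int(30 * FS)), sampling_rate=FS)
        assert not detect_artifacts(rec, k=3.0).any()

    def test_burst_flagged_with_jaccard_overlap(self, rng):
        x = rng.standard_normal(int(60 * FS)) * 0.1
        i0, i1 = int(20 * FS), int(22 * FS)
        x[i0:i1] += rng.standard_normal(i1 - i0) * 1.0  # 10x amplitude burst
        rec = EcgRecord(samples=x, sampling_rate=FS)
        mask = detect_artifacts(rec)
        truth = np.zeros_like(mask)
        truth[i0:i1] = True
        inter = (mask & truth).sum()
        union = (mask | truth).sum()
        assert inter / union >= 0.5

    def test_k_zero_flags_above_median(self, rng):
        rec = EcgRecord(samples=rng.standard_normal(int(40 * FS)), sampling_rate=FS)
        mask = detect_artifacts(rec, k=0.0)
        frac = mask.mean()
        assert 0.3 < frac < 0.7  # roughly the above-median half

    def test_too_short_rejected(self):
        rec = EcgRecord(samples=np.zeros(int(FS / 2)), sampling_rate=FS)
        with pytest.raises(ValueError):
            detect_artifacts(rec, window_s=1.0)

    def test_mitigate_empty_mask_is_identity(self, clean_record):
        out = mitigate_artifacts(clean_record, np.zeros(clean_record.samples.size, bool))
        np.testing.assert_array_equal(out.samples, clean_record.samples)

    def test_mitigate_untouched_outside_mask(self, clean_record):
        mask = np.zeros(clean_record.samples.size, bool)
        mask[1000:2000] = True
        out = mitigate_artifacts(clean_record, mask)
        np.testing.assert_array_equal(out.samples[~mask], clean_record.samples[~mask])
        assert not np.array_equal(out.samples[mask], clean_record.samples[mask])

    def test_mitigation_caps_burst_variance(self, rng):
        x = rng.standard_normal(int(60 * FS)) * 0.1
        i0, i1 = int(30 * FS), int(32 * FS)
        x[i0:i1] += rng.standard_normal(i1 - i0) * 1.0
        rec = EcgRecord(samples=x, sampling_rate=FS)
        mask = detect_artifacts(rec)
        out = mitigate_artifacts(rec, mask)
        win = int(FS)
        med = np.median(
            out.samples[: out.samples.size // win * win].reshape(-1, win).var(axis=1)
        )
        burst_var = out.samples[i0:i1].var()
        assert burst_var <= 2.0 * med


class TestGaps:
    def test_midpoint(self):
        out, _ = interpolate_gaps(
            np.array([1.0, 0.0, 3.0]), np.array([False, True, False]), max_fraction=1.0
        )
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])

    def test_identity_without_gaps(self):
        x = np.array([3.0, 1.0, 4.0, 1.0])
        out, _ = interpolate_gaps(x, np.zeros(4, bool))
        np.testing.assert_array_equal(out, x)

    def test_two_sample_gap(self):
        out, _ = interpolate_gaps(
            np.array([0.0, -1.0, -1.0, 6.0]),
            np.array([False, True, True, False]),
            max_fraction=1.0,
        )
        np.testing.assert_allclose(out, [0.0, 2.0, 4.0, 6.0])

    def test_fraction_at_limit_rejected(self):
        x = np.zeros(100)
        mask = np.zeros(100, bool)
        mask[50:52] = True  # exactly 2%
        with pytest.raises(ValueError, match="0.02"):
            interpolate_gaps(x, mask)

    def test_edge_gaps_trimmed(self):
        x = np.array([9.0] + list(range(100)), dtype=float)
        mask = np.zeros(101, bool)
        mask[0] = True
        out, _ = interpolate_gaps(x, mask, max_fraction=1.0)
        assert out.size == 100
        np.testing.assert_array_equal(out, np.arange(100.0))


class TestSnr:
    def test_equal_powers_give_zero_db(self):
        f = np.array([1.0, -1.0, 1.0, -1.0])
        r = np.array([2.0, 0.0, 2.0, 0.0])  # residual has unit power too
        assert compute_snr(f, r).snr_db == pytest.approx(0.0, abs=1e-12)

    def test_factor_100_gives_20_db(self, rng):
        f = rng.standard_normal(100000) * 10.0
        r = f + rng.standard_normal(100000)
        res = compute_snr(f, r)
        assert res.snr_db == pytest.approx(20.0, abs=0.1)

    def test_direct_evaluation(self, rng):
        f = rng.standard_normal(200000) * 2.0  # signal variance 4
        r = f + rng.standard_normal(200000)  # unit-variance noise
        assert compute_snr(f, r).snr_db == pytest.approx(10 * math.log10(4.0), abs=0.05)

    def test_zero_noise_is_infinite_sentinel(self):
        x = np.ones(10)
        assert compute_snr(x, x).snr_db == math.inf

    def test_noise_scaling_additivity(self, rng):
        f = rng.standard_normal(5000)
        n = rng.standard_normal(5000)
        a = compute_snr(f, f + n).snr_db
        b = compute_snr(f, f + math.sqrt(10.0) * n).snr_db
        assert a - b == pytest.approx(10.0, abs=1e-9)


class TestZscore:
    def test_symmetric_triple(self):
        z, stats = zscore([2.0, 4.0, 6.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert stats.mu == 4.0 and stats.sigma == 2.0

    def test_idempotent_on_standardized(self, rng):
        x = rng.standard_normal(500)
        z1, _ = zscore(x)
        z2, _ = zscore(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_four_point_example(self):
        z, stats = zscore([1.0, 2.0, 3.0, 4.0])
        assert stats.mu == pytest.approx(2.5)
        assert stats.sigma == pytest.approx(1.2909944, abs=1e-6)
        np.testing.assert_allclose(
            z, [-1.1618950, -0.3872983, 0.3872983, 1.1618950], atol=1e-6
        )

    def test_self_transform_yields_unit_stats(self, rng):
        x = rng.uniform(10, 20, 50)
        z, _ = zscore(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore([5.0, 5.0, 5.0])


class TestOutliers:
    def test_gaussian_tail_rate(self, rng):
        x = rng.standard_normal(10000)
        kept, removed = remove_outliers(x)
        assert removed.size / x.size < 0.01

    def test_single_pass_keeps_masked_spike(self):
        # with n=5 the spike is only 1.789 SDs from the mean: nothing removed
        kept, removed = remove_outliers([0.0, 0.0, 0.0, 0.0, 100.0])
        assert removed.size == 0
        assert kept.size == 5

    def test_all_equal_nothing_removed(self):
        kept, removed = remove_outliers([7.0] * 10)
        assert removed.size == 0


class TestWindows:
    @pytest.mark.parametrize("span,n", [(60.0, 1), (180.0, 5), (89.0, 1), (150.0, 4)])
    def test_window_counts(self, span, n):
        idx = make_windows(span)
        assert len(idx) == n
        starts = [w[0] for w in idx.windows]
        assert starts == [30.0 * i for i in range(n)]

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            make_windows(59.9)

    def test_interior_instants_covered_twice(self):
        idx = make_windows(240.0)
        last_end = idx.windows[-1][1]
        for t in np.arange(31.0, last_end - 31.0, 7.3):
            covering = sum(1 for s, e in idx.windows if s <= t < e)
            assert covering == 2


def test_full_chain_improves_true_snr():
    """Conditioning increases ground-truth SNR for corrupted records."""
    spec = clean_spec(duration_min=2.0, seed=31)
    rr = generate_rr_series(spec)
    clean = synthesize_ecg(rr, spec)
    noisy_spec = dataclasses.replace(
        spec,
        noise_profile=NoiseSpec(
            baseline_wander_amplitude=0.4,
            powerline_amplitude=0.1,
            motion_burst_rate=1.0,
            motion_burst_amplitude=0.8,
            gap_fraction=0.005,
        ),
    )
    noisy = synthesize_ecg(rr, noisy_spec)
    processed, log = preprocess_record(noisy)
    ref = bandpass_ecg(clean).samples
    n = processed.samples.size
    before = true_snr(noisy.samples[:n], clean.samples[:n])
    after = true_snr(processed.samples, ref[:n])
    assert after > before
    assert log.pct_interpolated > 0
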