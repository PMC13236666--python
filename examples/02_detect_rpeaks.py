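"""Condition a noisy ECG and detect R peaks, scored against ground truth.

The chain: gap interpolation, 0.5-40 Hz zero-phase band-pass, variance-based
artifact flagging with adaptive mitigation, then Pan-Tompkins-style detection
(derivative, squaring, 150 ms integration, adaptive dual thresholds).
"""

from ecgload import detect_rpeaks, preprocess_record, score_detection
from ecgload.synthetic import DEFAULT_NOISE, SessionSpec, generate_rr_series, synthesize_ecg

spec = SessionSpec(
    subject_id="demo", sex="male", session_type="training",
    duration_min=3.0, mean_hr=142.6, resting_hr=62.8, max_hr=200.9,
    lf_hf_target=1.33, rmssd_target=56.1, noise_profile=DEFAULT_NOISE, seed=7,
)
rr = generate_rr_series(spec)
record = synthesize_ecg(rr, spec)

processed, log = preprocess_record(record)
detected = detect_rpeaks(processed)
score = score_detection(detected, record.true_beat_times, tolerance_ms=50.0)

print(f"residual-based SNR  : {log.snr_in_db:.1f} -> {log.snr_out_db:.1f} dB")
print(f"samples interpolated: {log.pct_interpolated:.2f}%   flagged: {log.pct_flagged:.2f}%")
print(f"true beats          : {record.true_beat_times.size}")
print(f"detected beats      : {detected.n_beats}")
print(f"F1 at 50 ms         : {score.f1:.4f}")
print(f"mean |IBI error|    : {score.mean_abs_ibi_error_ms:.2f} ms")
# An F1 near 1 with millisecond-scale IBI error means the detected RR series
# is fit for HRV analysis despite the injected wander, hum and motion bursts.
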