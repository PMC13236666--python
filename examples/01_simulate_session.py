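"""Simulate one athlete session: modulated beat series plus a corrupted ECG.

The generator produces beat times from an integral-pulse-frequency-modulation
model whose LF/HF ratio, RMSSD and mean heart rate hit the requested targets,
then renders an ECG by placing a PQRST template at each beat and adding
baseline wander, powerline interference, motion bursts and short gaps.
"""

import numpy as np

from ecgload import NoiseSpec, SessionSpec, generate_rr_series, synthesize_ecg

spec = SessionSpec(
    subject_id="demo",
    sex="female",
    session_type="competition",
    duration_min=5.0,
    mean_hr=159.3,       # bpm
    resting_hr=66.5,     # bpm
    max_hr=214.3,        # bpm
    lf_hf_target=1.76,   # sympathovagal balance
    rmssd_target=49.5,   # ms
    noise_profile=NoiseSpec(
        baseline_wander_amplitude=0.3,
        powerline_amplitude=0.05,
        motion_burst_rate=0.5,
        motion_burst_amplitude=0.8,
        gap_fraction=0.01,
    ),
    seed=42,
)

rr = generate_rr_series(spec)
record = synthesize_ecg(rr, spec)

emp_rmssd = np.sqrt(np.mean(np.diff(rr.rr_ms) ** 2))
print(f"beats generated      : {rr.n_beats}")
print(f"empirical mean HR    : {60000.0 / rr.rr_ms.mean():.1f} bpm (target {spec.mean_hr})")
print(f"empirical RMSSD      : {emp_rmssd:.1f} ms (target {spec.rmssd_target})")
print(f"record length        : {record.duration_s:.1f} s at {record.sampling_rate:.0f} Hz")
print(f"samples masked as gap: {int(record.gap_mask.sum())} "
      f"({100 * record.gap_mask.mean():.2f}% of {record.samples.size})")
# The empirical values track the targets because the generator calibrates its
# modulation amplitudes; the gap count equals round(gap_fraction * n_samples).
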