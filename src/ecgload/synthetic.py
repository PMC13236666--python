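"""Synthetic session generator.

Emulates the statistical structure of multi-session single-lead ECG
monitoring in athletes: each session is one observational unit with a sex
label and a session class (training vs competition), an autonomically
modulated beat series, and realistic ECG corruption (baseline wander,
powerline interference, motion bursts, short recording gaps).

Beat times come from an integral pulse frequency modulation (IPFM) model:
the instantaneous cardiac period is the mean period plus two sinusoidal
surrogates centred in the low-frequency (0.1 Hz) and high-frequency
(0.25 Hz) autonomic bands, and a beat is emitted whenever the integral of
the instantaneous rate crosses an integer.  Sinusoidal band surrogates make
the spectral LF/HF ratio analytically controllable (it equals the squared
amplitude ratio), and a short fixed-point calibration matches the empirical
RMSSD and mean heart rate of the emitted series to the requested targets.

The ECG waveform is a fixed PQRST template (sum of Gaussians, dominant R
spike) placed at each beat time; morphology realism is deliberately out of
scope since only R-peak timing feeds the downstream pipeline.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .records import EcgRecord, RRSeries

LF_CENTER_HZ = 0.1
HF_CENTER_HZ = 0.25

SEX_MALE = "male"
SEX_FEMALE = "female"
TYPE_TRAINING = "training"
TYPE_COMPETITION = "competition"


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """ECG corruption levels.

    Amplitudes are mV; the wander drift frequency must stay below 0.5 Hz so
    the corruption lies in the band the 0.5-40 Hz filter removes.
    ``gap_fraction`` is the fraction of samples masked as missing and is
    capped at 0.02, the precondition for linear gap interpolation.
    """

    baseline_wander_amplitude: float = 0.0
    baseline_wander_freq: float = 0.2
    powerline_amplitude: float = 0.0
    powerline_freq: float = 50.0
    motion_burst_rate: float = 0.0  # bursts per minute
    motion_burst_amplitude: float = 0.0
    gap_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "baseline_wander_amplitude",
            "powerline_amplitude",
            "motion_burst_rate",
            "motion_burst_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gap_fraction <= 0.02:
            raise ValueError("gap_fraction must lie in [0, 0.02]")
        if not 0.0 < self.baseline_wander_freq < 0.5:
            raise ValueError("baseline_wander_freq must lie in (0, 0.5) Hz")

    @property
    def is_clean(self) -> bool:
        return (
            self.baseline_wander_amplitude == 0
            and self.powerline_amplitude == 0
            and self.motion_burst_rate == 0
            and self.gap_fraction == 0
        )


#: moderate ambulatory-style corruption used for cohort defaults
DEFAULT_NOISE = NoiseSpec(
    baseline_wander_amplitude=0.3,
    powerline_amplitude=0.05,
    motion_burst_rate=0.5,
    motion_burst_amplitude=0.8,
    gap_fraction=0.005,
)


@dataclasses.dataclass(frozen=True)
class SessionSpec:
    """Everything needed to deterministically generate one session."""

    subject_id: str
    sex: str
    session_type: str
    duration_min: float
    mean_hr: float
    resting_hr: float
    max_hr: float
    lf_hf_target: float
    rmssd_target: float
    noise_profile: NoiseSpec = dataclasses.field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in (SEX_MALE, SEX_FEMALE):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.session_type not in (TYPE_TRAINING, TYPE_COMPETITION):
            raise ValueError(f"unknown session_type {self.session_type!r}")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if not self.resting_hr < self.mean_hr <= self.max_hr:
            raise ValueError(
                "require resting_hr < mean_hr <= max_hr, got "
                f"{self.resting_hr} / {self.mean_hr} / {self.max_hr}"
            )
        if self.lf_hf_target <= 0:
            raise ValueError("lf_hf_target must be positive")
        if self.rmssd_target < 0:
            raise ValueError("rmssd_target must be >= 0")


class InfeasibleTargetError(ValueError):
    """Requested (mean HR, RMSSD, LF/HF) combination cannot be generated."""


LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def _modulation_plan(spec: SessionSpec) -> Tuple[float, float, float]:
    """Map (RMSSD, LF/HF) targets to tone amplitudes and white-jitter SD, ms.

    For a sinusoid of period-amplitude A sampled once per beat (period T0),
    successive differences have RMS sqrt(2) * A * |sin(pi f T0)|, so with an
    additional white beat-to-beat jitter of SD sigma_w

        RMSSD^2 = 2 A_lf^2 s_lf^2 + 2 A_hf^2 s_hf^2 + 2 sigma_w^2 .

    Tones alone are preferred.  At high RMSSD targets and short mean periods
    the required tone depth would push intervals below the physiological
    guard (the successive-difference transfer of a sub-0.4 Hz tone at ~2.4
    beats/s is weak), so the plan shifts power into the white component --
    whose flat spectrum contributes band power sigma_w^2 * width / nyquist
    to each band -- and re-solves the tone powers so the LF/HF ratio of the
    series still equals the target.
    """
    if spec.rmssd_target == 0:
        return 0.0, 0.0, 0.0
    t0_ms = 60000.0 / spec.mean_hr
    t0 = t0_ms / 1000.0
    s_lf = abs(np.sin(np.pi * LF_CENTER_HZ * t0))
    s_hf = abs(np.sin(np.pi * HF_CENTER_HZ * t0))
    rho = spec.lf_hf_target
    r2 = spec.rmssd_target**2
    denom = 4.0 * (rho * s_lf**2 + s_hf**2)

    budget = t0_ms - 260.0  # keep instantaneous period above the 250 ms guard
    if budget <= 0:
        raise InfeasibleTargetError(
            f"mean period {t0_ms:.0f} ms leaves no room above the 250 ms guard"
        )

    a_hf = np.sqrt(2.0 * r2 / denom)
    a_lf = np.sqrt(rho) * a_hf
    if a_lf + a_hf <= 0.9 * budget:
        return float(a_lf), float(a_hf), 0.0

    nyq = 1.0 / (2.0 * t0)  # beat-domain Nyquist, Hz
    b_lf = max(min(LF_BAND[1], nyq) - LF_BAND[0], 0.0)
    b_hf = max(min(HF_BAND[1], nyq) - HF_BAND[0], 0.0)
    for phi in np.linspace(0.05, 1.0, 96):
        sw2 = phi * r2 / 2.0
        w_lf = sw2 * b_lf / nyq
        w_hf = sw2 * b_hf / nyq
        p_hf = ((1.0 - phi) * r2 - 4.0 * s_lf**2 * (rho * w_hf - w_lf)) / denom
        if p_hf >= 0:
            p_lf = rho * (p_hf + w_hf) - w_lf
            if p_lf < 0:
                continue
        else:
            # white floor already exceeds the needed HF power; LF tone only
            p_hf = 0.0
            p_lf = max(rho * w_hf - w_lf, 0.0)
        a_lf = np.sqrt(2.0 * p_lf)
        a_hf = np.sqrt(2.0 * p_hf)
        if a_lf + a_hf + 2.5 * np.sqrt(sw2) <= budget:
            return float(a_lf), float(a_hf), float(np.sqrt(sw2))
    raise InfeasibleTargetError(
        "rmssd_target implies interval excursions below the physiological "
        f"guard at mean period {t0_ms:.0f} ms"
    )


def _ipfm_beat_times(
    t0_s: float,
    a_lf_s: float,
    a_hf_s: float,
    phases: Tuple[float, float],
    duration_s: float,
) -> np.ndarray:
    """Emit beat times from the integral of the instantaneous rate.

    Instantaneous period: T(t) = t0 + a_lf sin(2 pi f_lf t + p1)
                                    + a_hf sin(2 pi f_hf t + p2), seconds.
    Beats occur where M(t) = integral_0^t dt'/T(t') crosses integers.
    """
    if a_lf_s + a_hf_s >= 0.9 * t0_s:
        raise InfeasibleTargetError(
            "modulation depth implies non-positive instantaneous period: "
            f"amplitudes ({a_lf_s:.3f}+{a_hf_s:.3f}) s vs mean period {t0_s:.3f} s"
        )
    # margin absorbs the random-walk span shrink of beat-level jitter
    horizon = duration_s + 10.0 + 3.0 * t0_s
    dt = min(0.01, t0_s / 16.0)
    grid = np.arange(0.0, horizon + dt, dt)
    period = (
        t0_s
        + a_lf_s * np.sin(2 * np.pi * LF_CENTER_HZ * grid + phases[0])
        + a_hf_s * np.sin(2 * np.pi * HF_CENTER_HZ * grid + phases[1])
    )
    rate = 1.0 / period
    m = np.concatenate(([0.0], np.cumsum((rate[1:] + rate[:-1]) * 0.5 * dt)))
    n_beats = int(np.floor(m[-1]))
    k = np.arange(0, n_beats + 1, dtype=float)
    beats = np.interp(k, m, grid)
    # one Newton polish per beat (vectorised): M is monotone, M' = rate
    for _ in range(2):
        per_b = (
            t0_s
            + a_lf_s * np.sin(2 * np.pi * LF_CENTER_HZ * beats + phases[0])
            + a_hf_s * np.sin(2 * np.pi * HF_CENTER_HZ * beats + phases[1])
        )
        m_b = np.interp(beats, grid, m)
        beats = beats - (m_b - k) * per_b
    beats = beats[beats <= horizon]
    return np.maximum.accumulate(beats) if beats.size else beats


def generate_rr_series(spec: SessionSpec) -> RRSeries:
    """Generate an RR series whose LF/HF ratio, RMSSD and mean HR match the spec.

    The sinusoid amplitudes and the mean period are refined by a short
    fixed-point calibration (at most three passes) so the *empirical*
    RMSSD lands within the generator contract (15% of target) and the mean
    heart rate within 2 bpm, even at the large modulation depths implied by
    high-RMSSD targets where the first-order map is biased.
    """
    rng = np.random.default_rng(spec.seed)
    phases = tuple(rng.uniform(0.0, 2 * np.pi, size=2))
    jitter_seq = np.random.SeedSequence([spec.seed, 104729])
    duration_s = spec.duration_min * 60.0

    a_lf_ms, a_hf_ms, sigma_w_ms = _modulation_plan(spec)
    t0_s = 60.0 / spec.mean_hr
    target_rr_ms = 60000.0 / spec.mean_hr

    beats = None
    for it in range(4):
        beats = _ipfm_beat_times(
            t0_s, a_lf_ms / 1000.0, a_hf_ms / 1000.0, phases, duration_s
        )
        if beats.size < 3:
            raise InfeasibleTargetError("spec produced fewer than 3 beats")
        rr = 1000.0 * np.diff(beats)
        if sigma_w_ms > 0:
            # beat-to-beat white jitter, clipped at 3 SD to respect the guard;
            # same jitter stream every calibration pass for determinism
            jrng = np.random.default_rng(jitter_seq)
            w = np.clip(
                jrng.standard_normal(rr.size) * sigma_w_ms,
                -3.0 * sigma_w_ms,
                3.0 * sigma_w_ms,
            )
            rr = rr + w
            beats = beats[0] + np.concatenate(([0.0], np.cumsum(rr / 1000.0)))
        emp_mean = float(np.mean(rr))
        emp_rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2))) if rr.size > 1 else 0.0
        mean_ok = abs(60000.0 / emp_mean - spec.mean_hr) < 0.5
        rmssd_ok = (
            spec.rmssd_target == 0
            or abs(emp_rmssd - spec.rmssd_target) <= 0.05 * spec.rmssd_target
        )
        if mean_ok and rmssd_ok:
            break
        t0_s += (target_rr_ms - emp_mean) / 1000.0
        if t0_s <= 0:
            raise InfeasibleTargetError("mean-period calibration diverged")
        if spec.rmssd_target > 0 and emp_rmssd > 0:
            scale = spec.rmssd_target / emp_rmssd
            a_lf_ms *= scale
            a_hf_ms *= scale
            sigma_w_ms *= scale

    # start the session mid-cycle so the first beat sits away from the edge
    beats = beats + rng.uniform(0.3, 0.7) * t0_s
    series = RRSeries.from_beat_times(beats, enforce_guard=True)
    if series.span_s < duration_s - 1.0:
        raise InfeasibleTargetError("generated span shorter than requested duration")
    return series


# ---------------------------------------------------------------------------
# ECG waveform synthesis

#: PQRST template as (time offset s, amplitude mV, width s) Gaussians
_PQRST = (
    (-0.20, 0.12, 0.025),  # P
    (-0.03, -0.10, 0.010),  # Q
    (0.00, 1.00, 0.010),  # R
    (0.03, -0.15, 0.010),  # S
    (0.22, 0.25, 0.040),  # T
)
_TEMPLATE_HALF_S = 0.35


def pqrst_template(fs: float) -> Tuple[np.ndarray, int]:
    """Sampled PQRST template and the index of its R peak."""
    t = np.arange(-_TEMPLATE_HALF_S, _TEMPLATE_HALF_S + 1.0 / fs, 1.0 / fs)
    wave = np.zeros_like(t)
    for offset, amp, width in _PQRST:
        wave += amp * np.exp(-0.5 * ((t - offset) / width) ** 2)
    return wave, int(np.argmin(np.abs(t)))


def synthesize_ecg(rr: RRSeries, spec: SessionSpec, fs: float = 250.0) -> EcgRecord:
    """Place the PQRST template at each beat time and add NoiseSpec corruption."""
    if fs < 125.0:
        raise ValueError("sampling rate must be >= 125 Hz")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
    noise = spec.noise_profile

    span = rr.beat_times[-1] + 0.5
    n = int(round(span * fs))
    samples = np.zeros(n)

    template, r_idx = pqrst_template(fs)
    beat_idx = np.round(rr.beat_times * fs).astype(int)
    starts = beat_idx - r_idx
    offs = np.arange(template.size)
    idx = starts[:, None] + offs[None, :]
    valid = (idx >= 0) & (idx < n)
    np.add.at(samples, idx[valid], np.broadcast_to(template, idx.shape)[valid])

    t = np.arange(n) / fs
    if noise.baseline_wander_amplitude > 0:
        samples += noise.baseline_wander_amplitude * np.sin(
            2 * np.pi * noise.baseline_wander_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amplitude > 0:
        samples += noise.powerline_amplitude * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
        )

    burst_windows: List[Tuple[int, int]] = []
    if noise.motion_burst_rate > 0 and noise.motion_burst_amplitude > 0:
        n_bursts = rng.poisson(noise.motion_burst_rate * span / 60.0)
        for _ in range(n_bursts):
            dur = rng.uniform(1.0, 3.0)
            start = rng.uniform(0.0, max(span - dur, 0.0))
            i0, i1 = int(start * fs), min(int((start + dur) * fs), n)
            samples[i0:i1] += noise.motion_burst_amplitude * rng.standard_normal(i1 - i0)
            burst_windows.append((i0, i1))

    gap_mask = np.zeros(n, dtype=bool)
    total_gap = int(round(noise.gap_fraction * n))
    if total_gap > 0:
        run_len = min(int(fs), total_gap)  # ~1 s runs
        n_runs = max(total_gap // run_len, 1)
        lens = np.full(n_runs, total_gap // n_runs)
        lens[: total_gap - int(lens.sum())] += 1
        # one run per interior segment keeps runs disjoint and interior
        margin = int(fs)
        seg_edges = np.linspace(margin, n - margin, n_runs + 1).astype(int)
        for j, length in enumerate(lens):
            lo, hi = seg_edges[j], seg_edges[j + 1] - int(length)
            start = int(rng.integers(lo, max(hi, lo + 1)))
            gap_mask[start : start + int(length)] = True
        samples[gap_mask] = 0.0

    record = EcgRecord(
        samples=samples,
        sampling_rate=fs,
        gap_mask=gap_mask,
        meta=spec,
        true_beat_times=rr.beat_times.copy(),
    )
    record.burst_windows = burst_windows  # generator-only schedule, for tests
    return record


# ---------------------------------------------------------------------------
# Cohort generation

#: per-class population parameters (mean, SD) emulating the two session
#: classes of athlete monitoring: competition has higher mean HR, lower
#: RMSSD/SDNN and higher LF/HF than training.
CLASS_EFFECT_DEFAULTS: Dict[str, Dict[str, Tuple[float, float]]] = {
    TYPE_TRAINING: {
        "mean_hr": (142.6, 11.8),
        "resting_hr": (62.8, 7.9),
        "hr_reserve": (138.1, 12.3),
        "rmssd": (56.1, 13.7),
        "lf_hf": (1.33, 0.41),
        "duration_min": (40.0, 4.0),
    },
    TYPE_COMPETITION: {
        "mean_hr": (159.3, 14.9),
        "resting_hr": (66.5, 8.3),
        "hr_reserve": (147.8, 13.1),
        "rmssd": (49.5, 15.2),
        "lf_hf": (1.76, 0.53),
        "duration_min": (60.0, 6.0),
    },
}


def _draw(rng: np.random.Generator, mu_sd: Tuple[float, float], lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(*mu_sd), lo, hi))


def _feasible_rmssd(rmssd: float, mean_hr: float, lf_hf: float) -> float:
    """Largest RMSSD at/below the draw that the modulation plan can realise.

    High RMSSD draws at short mean periods would push intervals below the
    physiological guard; the cohort sampler shrinks such draws to the
    feasible region rather than rejecting the session.
    """
    probe = SessionSpec(
        "probe", SEX_MALE, TYPE_TRAINING, 1.0,
        mean_hr, mean_hr - 50.0, mean_hr + 60.0, lf_hf, rmssd,
    )
    for _ in range(12):
        try:
            _modulation_plan(probe)
            return probe.rmssd_target
        except InfeasibleTargetError:
            probe = dataclasses.replace(probe, rmssd_target=probe.rmssd_target * 0.85)
    return 5.0


def cohort_specs(
    n_subjects: int,
    sessions_per_subject: int,
    class_effects: Optional[Dict[str, Dict[str, Tuple[float, float]]]] = None,
    seed: int = 0,
    noise: Optional[NoiseSpec] = None,
    duration_min: Optional[float] = None,
) -> List[SessionSpec]:
    """Balanced training/competition session specs for a synthetic cohort.

    Sessions alternate between the two classes within each subject so the
    cohort is class-balanced whenever ``sessions_per_subject`` is even.
    ``duration_min`` overrides the class-specific duration draw (useful for
    small, fast test cohorts).
    """
    if n_subjects <= 0 or sessions_per_subject <= 0:
        raise ValueError("counts must be positive")
    effects = class_effects or CLASS_EFFECT_DEFAULTS
    if noise is None:
        noise = DEFAULT_NOISE
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)
    specs: List[SessionSpec] = []
    for i in range(n_subjects):
        sex = SEX_MALE if i % 2 == 0 else SEX_FEMALE
        session_seeds = subject_seeds[i].spawn(sessions_per_subject)
        for j in range(sessions_per_subject):
            stype = TYPE_TRAINING if (i + j) % 2 == 0 else TYPE_COMPETITION
            p = effects[stype]
            rng = np.random.default_rng(session_seeds[j])
            rhr = _draw(rng, p["resting_hr"], 40.0, 90.0)
            reserve = _draw(rng, p["hr_reserve"], 100.0, 180.0)
            max_hr = rhr + reserve
            mean_hr = _draw(rng, p["mean_hr"], rhr + 30.0, max_hr - 5.0)
            lf_hf = _draw(rng, p["lf_hf"], 0.3, 5.0)
            rmssd = _feasible_rmssd(
                _draw(rng, p["rmssd"], 5.0, 120.0), mean_hr, lf_hf
            )
            dur = (
                duration_min
                if duration_min is not None
                else _draw(rng, p["duration_min"], 10.0, 120.0)
            )
            specs.append(
                SessionSpec(
                    subject_id=f"S{i:03d}",
                    sex=sex,
                    session_type=stype,
                    duration_min=dur,
                    mean_hr=mean_hr,
                    resting_hr=rhr,
                    max_hr=max_hr,
                    lf_hf_target=lf_hf,
                    rmssd_target=rmssd,
                    noise_profile=noise,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return specs


def generate_cohort(
    n_subjects: int,
    sessions_per_subject: int,
    class_effects: Optional[Dict[str, Dict[str, Tuple[float, float]]]] = None,
    seed: int = 0,
    noise: Optional[NoiseSpec] = None,
    fs: float = 250.0,
    duration_min: Optional[float] = None,
) -> List[EcgRecord]:
    """Generate a cohort of ECG records, balanced across session classes."""
    specs = cohort_specs(
        n_subjects,
        sessions_per_subject,
        class_effects=class_effects,
        seed=seed,
        noise=noise,
        duration_min=duration_min,
    )
    return [synthesize_ecg(generate_rr_series(s), s, fs=fs) for s in specs]
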