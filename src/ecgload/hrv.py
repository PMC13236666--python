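"""Heart-rate-variability feature extraction.

Per 60-s window: time-domain features (mean HR, RMSSD, SDNN).  Per session:
frequency-domain band powers (LF 0.04-0.15 Hz, HF 0.15-0.40 Hz, from the RR
series cubic-resampled to a uniform 4 Hz grid and Welch-estimated) and
nonlinear descriptors (Poincare SD1/SD2, sample entropy).  Windowed
features are aggregated to the session level by the mean over valid
windows; the resting-heart-rate proxy is the 5th percentile of windowed
mean HR.

SD conventions: RMSSD, SD1 and SD2 use the population convention (and SD1
treats the successive-difference mean as zero, the standard Poincare
reading), which makes SD1 = RMSSD / sqrt(2) an exact identity; SDNN uses
the sample convention (n-1), matching common HRV practice.

Spectral caveat: 60-s windows cannot resolve 0.04 Hz content, so LF/HF is
computed on the session-long RR series (5-minute minimum recommended) and
windows feed the time-domain features only.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .preprocess import make_windows
from .records import QUALITY_SUSPECT, RRSeries
from .synthetic import SessionSpec

logger = logging.getLogger(__name__)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 60.0

#: canonical predictor roster (feature-table column order)
FEATURE_COLUMNS = [
    "mean_hr",
    "resting_hr",
    "hr_reserve",
    "rmssd",
    "sdnn",
    "lf_power",
    "hf_power",
    "lf_hf",
]
NONLINEAR_COLUMNS = ["sd1", "sd2", "sample_entropy"]


@dataclasses.dataclass(frozen=True)
class SpectralFeatures:
    lf_power: float
    hf_power: float
    lf_hf: Optional[float]
    total_power: float
    method: str = "welch-4hz-cubic"


@dataclasses.dataclass
class SessionFeatures:
    mean_hr: float
    resting_hr: float
    hr_reserve: float
    rmssd: float
    sdnn: float
    lf_power: float
    hf_power: float
    lf_hf: Optional[float]
    sd1: float
    sd2: float
    sample_entropy: float
    n_windows: int
    breathing_rate: Optional[float] = None


def time_domain(rr: RRSeries | np.ndarray) -> Tuple[float, float, float]:
    """(RMSSD ms, SDNN ms, mean HR bpm) of the usable intervals.

    RMSSD is the root mean square of successive differences (population
    convention); SDNN the sample SD of intervals; mean HR = 60000 / mean RR.
    """
    x = rr.usable() if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 usable intervals")
    diffs = np.diff(x)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    sdnn = float(np.std(x, ddof=1))
    mean_hr = 60000.0 / float(np.mean(x))
    return rmssd, sdnn, mean_hr


def spectral(rr: RRSeries, min_span_s: float = 60.0) -> SpectralFeatures:
    """Band powers of the RR series on a uniform 4 Hz grid (Welch PSD).

    The series is cubic-interpolated at interval end times, mean-detrended,
    and Welch-estimated with 60-s segments at half overlap.  An HF power of
    zero yields a missing (None) LF/HF ratio rather than an infinity.
    """
    if rr.span_s < min_span_s:
        raise ValueError(f"span {rr.span_s:.0f} s below the {min_span_s:.0f}-s minimum")
    if rr.rr_ms.size < 30:
        raise ValueError("need at least 30 intervals for a spectral estimate")
    t = rr.beat_times[1:]
    cs = CubicSpline(t, rr.rr_ms)
    grid = np.arange(t[0], t[-1], 1.0 / RESAMPLE_HZ)
    x = cs(grid)
    x = x - x.mean()
    nperseg = min(x.size, int(WELCH_SEGMENT_S * RESAMPLE_HZ))
    freqs, psd = welch(x, fs=RESAMPLE_HZ, nperseg=nperseg, noverlap=nperseg // 2)

    def band_power(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[m], freqs[m])) if m.sum() > 1 else 0.0

    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    total = band_power(freqs[1], freqs[-1] + 1e-9)
    ratio = lf / hf if hf > 0 else None
    return SpectralFeatures(lf_power=lf, hf_power=hf, lf_hf=ratio, total_power=total)


def poincare(rr: RRSeries | np.ndarray) -> Tuple[float, float]:
    """Poincare descriptors (SD1, SD2) in ms, population convention.

    SD1 is the RMS of successive differences / sqrt(2) (dispersion
    perpendicular to the identity line, difference mean taken as zero), so
    SD1 == RMSSD / sqrt(2) exactly; SD2 is the SD of successive sums /
    sqrt(2) (dispersion along the identity line).
    """
    x = rr.usable() if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 intervals")
    diffs = np.diff(x)
    sums = x[1:] + x[:-1]
    sd1 = float(np.sqrt(np.mean(diffs**2)) / math.sqrt(2.0))
    sd2 = float(np.std(sums, ddof=0) / math.sqrt(2.0))
    return sd1, sd2


def sample_entropy(
    rr: RRSeries | np.ndarray,
    m: int = 2,
    r: float = 0.2,
    max_intervals: int = 2000,
) -> float:
    """SampEn(m, r*SD, N): -ln(A/B) with Chebyshev distance, no self-matches.

    A counts template matches of length m+1, B of length m.  Long series
    are truncated at ``max_intervals`` (the estimate stabilises well below
    that; the truncation bounds the O(N^2) cost).  Returns NaN when no
    template pair matches.
    """
    x = rr.usable() if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if m < 1 or r <= 0:
        raise ValueError("require m >= 1 and r > 0")
    if x.size < 100:
        raise ValueError("need at least 100 intervals for a stable estimate")
    x = x[:max_intervals]
    tol = r * float(np.std(x, ddof=0))
    n_tpl = x.size - m  # same template count at both lengths (standard convention)

    def count_matches(mm: int) -> int:
        templates = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_tpl]
        total = 0
        for i in range(n_tpl - 1):
            d = np.max(np.abs(templates[i + 1 :] - templates[i]), axis=1)
            total += int(np.count_nonzero(d <= tol))
        return total

    b = count_matches(m)
    a = count_matches(m + 1)
    if a == 0 or b == 0:
        logger.info("sample entropy undefined: A=%d B=%d", a, b)
        return float("nan")
    return float(-math.log(a / b))


@dataclasses.dataclass
class WindowFeatures:
    start_s: float
    end_s: float
    rmssd: float
    sdnn: float
    mean_hr: float


def windowed_time_domain(rr: RRSeries) -> List[WindowFeatures]:
    """Time-domain features per 60-s half-overlap window (invalid windows dropped)."""
    index = make_windows(rr.span_s)
    t0 = rr.beat_times[0]
    out: List[WindowFeatures] = []
    for start, end in index.windows:
        sel = (rr.beat_times[1:] >= t0 + start) & (rr.beat_times[1:] < t0 + end)
        sel &= rr.quality != QUALITY_SUSPECT
        intervals = rr.rr_ms[sel]
        if intervals.size < 3:
            logger.info("window [%.0f, %.0f) dropped: too few intervals", start, end)
            continue
        rmssd, sdnn, mean_hr = time_domain(intervals)
        out.append(WindowFeatures(start, end, rmssd, sdnn, mean_hr))
    return out


def session_aggregate(
    per_window: Sequence[WindowFeatures],
    meta: Optional[SessionSpec] = None,
) -> dict:
    """Mean-over-windows aggregation plus the RHR / HR-reserve rules.

    Resting and maximum HR are baseline cardiovascular indicators: they
    come from the session metadata when present.  Without metadata the
    resting-HR proxy is the 5th percentile of windowed mean HR and the
    maximum is the observed windowed maximum (both logged as proxies).
    """
    if not per_window:
        raise ValueError("no valid windows: session dropped")
    hrs = np.array([w.mean_hr for w in per_window])
    if meta is not None:
        resting = float(meta.resting_hr)
        max_hr = float(meta.max_hr)
    else:
        logger.info("no metadata: resting/max HR fall back to in-session proxies")
        resting = float(np.percentile(hrs, 5.0))
        max_hr = float(hrs.max())
    return {
        "mean_hr": float(hrs.mean()),
        "resting_hr": resting,
        "hr_reserve": max_hr - resting,
        "rmssd": float(np.mean([w.rmssd for w in per_window])),
        "sdnn": float(np.mean([w.sdnn for w in per_window])),
        "n_windows": len(per_window),
    }


def session_features(rr: RRSeries, meta: Optional[SessionSpec] = None) -> SessionFeatures:
    """Full per-session feature vector: windowed time-domain aggregation,
    session-long spectral estimate, and nonlinear descriptors."""
    per_window = windowed_time_domain(rr)
    agg = session_aggregate(per_window, meta)
    spec = spectral(rr)
    sd1, sd2 = poincare(rr)
    try:
        sampen = sample_entropy(rr)
    except ValueError:
        sampen = float("nan")
    return SessionFeatures(
        mean_hr=agg["mean_hr"],
        resting_hr=agg["resting_hr"],
        hr_reserve=agg["hr_reserve"],
        rmssd=agg["rmssd"],
        sdnn=agg["sdnn"],
        lf_power=spec.lf_power,
        hf_power=spec.hf_power,
        lf_hf=spec.lf_hf,
        sd1=sd1,
        sd2=sd2,
        sample_entropy=sampen,
        n_windows=agg["n_windows"],
    )
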