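"""Core data containers shared across the pipeline.

``EcgRecord`` carries a raw or filtered single-lead ECG trace together with
its sampling grid, a per-sample gap mask, optional session metadata and --
for synthetic records -- the ground-truth beat times used to score the
detector.  ``RRSeries`` carries detected (or simulated) beat times and the
derived inter-beat intervals with a per-interval quality flag.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import SessionSpec

QUALITY_OK = "ok"
QUALITY_INTERPOLATED = "interpolated"
QUALITY_SUSPECT = "suspect"

#: physiological guard on inter-beat intervals, ms
RR_MIN_MS = 250.0
RR_MAX_MS = 3000.0


@dataclasses.dataclass
class EcgRecord:
    """Single-lead ECG trace in mV on a uniform sampling grid."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    gap_mask: Optional[np.ndarray] = None
    meta: Optional["SessionSpec"] = None
    true_beat_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate < 125.0:
            raise ValueError(
                f"sampling_rate must be >= 125 Hz, got {self.sampling_rate}"
            )
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.samples.size, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.size != self.samples.size:
            raise ValueError("gap_mask and samples must have equal length")
        if self.true_beat_times is not None:
            self.true_beat_times = np.asarray(self.true_beat_times, dtype=float)
            if np.any(np.diff(self.true_beat_times) <= 0):
                raise ValueError("true_beat_times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Copy of the record carrying new sample values (metadata kept)."""
        return EcgRecord(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate,
            start_time=self.start_time,
            gap_mask=self.gap_mask.copy(),
            meta=self.meta,
            true_beat_times=None
            if self.true_beat_times is None
            else self.true_beat_times.copy(),
        )


@dataclasses.dataclass
class RRSeries:
    """Beat times (s) and inter-beat intervals (ms) with quality flags.

    ``rr_ms[i] = 1000 * (beat_times[i+1] - beat_times[i])``; the quality
    flag is per interval and one of ``ok`` / ``interpolated`` / ``suspect``.
    """

    beat_times: np.ndarray
    rr_ms: np.ndarray
    quality: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.quality = np.asarray(self.quality, dtype=object)
        if self.rr_ms.size != max(self.beat_times.size - 1, 0):
            raise ValueError("len(rr_ms) must equal len(beat_times) - 1")
        if self.quality.size != self.rr_ms.size:
            raise ValueError("quality must be one flag per interval")
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.rr_ms <= 0):
            raise ValueError("all rr_ms must be positive")
        ok = self.quality == QUALITY_OK
        if np.any(ok):
            bad = (self.rr_ms[ok] < RR_MIN_MS) | (self.rr_ms[ok] > RR_MAX_MS)
            if np.any(bad):
                raise ValueError(
                    "intervals flagged 'ok' must lie in the physiological "
                    f"guard [{RR_MIN_MS}, {RR_MAX_MS}] ms"
                )

    @classmethod
    def from_beat_times(cls, beat_times: np.ndarray, enforce_guard: bool = True) -> "RRSeries":
        beat_times = np.asarray(beat_times, dtype=float)
        rr = 1000.0 * np.diff(beat_times)
        quality = np.full(rr.size, QUALITY_OK, dtype=object)
        if enforce_guard:
            outside = (rr < RR_MIN_MS) | (rr > RR_MAX_MS)
            quality[outside] = QUALITY_SUSPECT
        return cls(beat_times=beat_times, rr_ms=rr, quality=quality)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def span_s(self) -> float:
        if self.beat_times.size < 2:
            return 0.0
        return float(self.beat_times[-1] - self.beat_times[0])

    def usable(self) -> np.ndarray:
        """Intervals fit for HRV computation (ok or interpolated)."""
        keep = self.quality != QUALITY_SUSPECT
        return self.rr_ms[keep]
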