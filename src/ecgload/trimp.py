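"""Banister-form Training Impulse (TRIMP) targets and the leakage audit.

TRIMP = sum_i D_i * dHR_i * exp(b * dHR_i), with D_i the interval duration
in minutes, dHR the normalized heart-rate reserve
(HR_ex - HR_rest) / (HR_max - HR_rest) clamped to [0, 1], and b the
sex-specific weighting (1.92 male, 1.67 female) capturing the exponential
relationship between relative intensity and physiological stress.  When
``interval_basis`` is ``whole_session`` the sum collapses to the
single-term product D * dHR * exp(b * dHR).

Sessions are stratified into low / medium / high intensity by empirical
TRIMP tertiles.  The leakage audit bars the target and its derivatives
(TRIMP, ACWR, and any affine alias detected by |Pearson r| == 1) from the
predictor roster; near-circular physiological predictors such as mean HR
are retained by design.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

B_MALE = 1.92
B_FEMALE = 1.67

STRATA = ("low", "medium", "high")


@dataclasses.dataclass(frozen=True)
class TrimpConfig:
    b_male: float = B_MALE
    b_female: float = B_FEMALE
    interval_basis: str = "per_window"  # per_window | whole_session

    def __post_init__(self) -> None:
        if self.b_male <= 0 or self.b_female <= 0:
            raise ValueError("b coefficients must be positive")
        if self.interval_basis not in ("per_window", "whole_session"):
            raise ValueError(f"unknown interval_basis {self.interval_basis!r}")

    def b_for(self, sex: str) -> float:
        if sex == "male":
            return self.b_male
        if sex == "female":
            return self.b_female
        raise ValueError(f"sex must be male/female, got {sex!r}")


@dataclasses.dataclass
class TrimpResult:
    trimp: float
    delta_hr: np.ndarray
    durations_min: np.ndarray
    b_used: float
    stratum: Optional[str] = None


def delta_hr(
    hr_ex: Union[float, np.ndarray], hr_rest: float, hr_max: float
) -> Union[float, np.ndarray]:
    """Normalized heart-rate reserve, clamped to [0, 1]."""
    if hr_max <= hr_rest:
        raise ValueError(f"hr_max ({hr_max}) must exceed hr_rest ({hr_rest})")
    out = (np.asarray(hr_ex, dtype=float) - hr_rest) / (hr_max - hr_rest)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(hr_ex) or out.ndim == 0 else out


def compute_trimp(
    hr_series: Sequence[float],
    durations_min: Sequence[float],
    sex: str,
    hr_rest: float,
    hr_max: float,
    cfg: TrimpConfig = TrimpConfig(),
) -> TrimpResult:
    """Per-interval Banister TRIMP from windowed mean HR and durations.

    With ``whole_session`` basis, the duration-weighted mean HR and total
    duration form the single-term product variant.
    """
    hr = np.asarray(hr_series, dtype=float)
    dur = np.asarray(durations_min, dtype=float)
    if hr.size == 0:
        raise ValueError("empty HR series")
    if hr.size != dur.size:
        raise ValueError("hr_series and durations must align")
    if np.any(dur <= 0):
        raise ValueError("durations must be positive")
    b = cfg.b_for(sex)
    if cfg.interval_basis == "whole_session":
        total = float(dur.sum())
        mean_hr = float(np.average(hr, weights=dur))
        dhr = np.array([delta_hr(mean_hr, hr_rest, hr_max)])
        dur = np.array([total])
    else:
        dhr = np.asarray(delta_hr(hr, hr_rest, hr_max), dtype=float)
    trimp = float(np.sum(dur * dhr * np.exp(b * dhr)))
    return TrimpResult(trimp=trimp, delta_hr=dhr, durations_min=dur, b_used=b)


def stratify(trimp_values: Sequence[float]) -> np.ndarray:
    """Tertile strata (low/medium/high) from empirical 1/3 and 2/3 quantiles.

    Left-closed bins with boundary ties going to the lower stratum;
    order-invariant in the input.
    """
    v = np.asarray(trimp_values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 sessions to stratify")
    if np.all(v == v[0]):
        raise ValueError("all TRIMP values identical: no stratification possible")
    q1, q2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(v <= q1, "low", np.where(v <= q2, "medium", "high"))
    return labels.astype(object)


@dataclasses.dataclass
class AuditReport:
    retained: List[str]
    dropped: Dict[str, str]  # column -> reason
    passed: bool


class LeakageError(RuntimeError):
    """The target itself appears among the predictors."""


_BANNED_NAMES = ("trimp", "acwr")


def leakage_audit(
    feature_table: pd.DataFrame,
    target: Sequence[float],
    atol: float = 1e-9,
) -> AuditReport:
    """Bar TRIMP-derived quantities from the predictor roster.

    Drops columns named after the target or its derivatives (TRIMP, ACWR)
    and columns that are an affine transform of the target (|Pearson r| = 1
    within tolerance).  A column *identical* to the target is a hard
    failure.  An empty table passes vacuously with a warning.
    """
    target = np.asarray(target, dtype=float)
    if feature_table.shape[1] == 0:
        warnings.warn("empty feature table: audit passes vacuously", stacklevel=2)
        return AuditReport(retained=[], dropped={}, passed=True)

    retained: List[str] = []
    dropped: Dict[str, str] = {}
    for col in feature_table.columns:
        name = str(col).lower()
        values = feature_table[col]
        if np.issubdtype(values.dtype, np.number) and np.allclose(
            values.to_numpy(dtype=float), target, rtol=0.0, atol=atol
        ):
            raise LeakageError(f"column {col!r} is the target itself")
        if any(tag in name for tag in _BANNED_NAMES):
            dropped[str(col)] = "target-derived name"
            continue
        if np.issubdtype(values.dtype, np.number) and target.std() > 0:
            x = values.to_numpy(dtype=float)
            if x.std() > 0:
                r = float(np.corrcoef(x, target)[0, 1])
                if abs(r) >= 1.0 - atol:
                    dropped[str(col)] = "affine alias of target"
                    continue
        retained.append(str(col))
    return AuditReport(retained=retained, dropped=dropped, passed=True)


def build_targets(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    cfg: TrimpConfig = TrimpConfig(),
) -> pd.DataFrame:
    """Session TRIMP targets from a feature table and a session manifest.

    ``features`` must carry ``mean_hr``; ``manifest`` (indexed like
    ``features``) carries sex, duration_min, resting and maximum HR.  The
    per-session TRIMP here uses the session mean HR over the session
    duration; pipelines with per-window HR traces should call
    :func:`compute_trimp` directly.
    """
    rows = []
    for idx in features.index:
        m = manifest.loc[idx]
        res = compute_trimp(
            [features.loc[idx, "mean_hr"]],
            [m["duration_min"]],
            m["sex"],
            m["resting_hr"],
            m["max_hr"],
            cfg=cfg,
        )
        rows.append({"session_id": idx, "trimp": res.trimp, "b_used": res.b_used})
    out = pd.DataFrame(rows).set_index("session_id")
    out["stratum"] = stratify(out["trimp"].to_numpy())
    return out
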