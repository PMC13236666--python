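"""End-to-end orchestration: sessions -> features -> targets -> models.

Two entry paths exist: the full signal path (ECG record -> preprocessing ->
R-peak detection -> RR cleaning) and the direct RR path used when beat
series are already available.  Both converge on the per-session feature
vector, the TRIMP target and the leakage-audited predictor table.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hrv import FEATURE_COLUMNS, NONLINEAR_COLUMNS, session_features, windowed_time_domain
from .preprocess import preprocess_record
from .records import EcgRecord, RRSeries
from .rpeaks import clean_rr, detect_rpeaks
from .synthetic import SessionSpec, cohort_specs, generate_rr_series
from .trimp import TrimpConfig, compute_trimp, leakage_audit, stratify

logger = logging.getLogger(__name__)


def ecg_to_rr(record: EcgRecord) -> RRSeries:
    """Condition an ECG record, detect R peaks and clean the RR series."""
    processed, log = preprocess_record(record)
    logger.info(
        "preprocess: SNR %.1f -> %.1f dB, %.2f%% interpolated, %.2f%% flagged",
        log.snr_in_db, log.snr_out_db, log.pct_interpolated, log.pct_flagged,
    )
    return clean_rr(detect_rpeaks(processed))


def session_row(rr: RRSeries, spec: SessionSpec) -> dict:
    """One feature-table row (predictors + nonlinear descriptors)."""
    feats = session_features(rr, spec)
    row = {c: getattr(feats, c) for c in FEATURE_COLUMNS + NONLINEAR_COLUMNS}
    row["n_windows"] = feats.n_windows
    return row


def session_trimp(
    rr: RRSeries, spec: SessionSpec, cfg: TrimpConfig = TrimpConfig()
) -> float:
    """Session TRIMP from windowed mean HR (hop-length intervals).

    Each 60-s half-overlap window contributes one interval of hop length
    (0.5 min), so interval durations tile the analysed span once; resting
    and maximum HR come from the session metadata.
    """
    windows = windowed_time_domain(rr)
    if not windows:
        raise ValueError("no valid windows for TRIMP computation")
    hrs = [w.mean_hr for w in windows]
    hop_min = 0.5
    durations = [hop_min] * len(hrs)
    return compute_trimp(
        hrs, durations, spec.sex, spec.resting_hr, spec.max_hr, cfg=cfg
    ).trimp


def build_dataset(
    n_subjects: int = 50,
    sessions_per_subject: int = 4,
    seed: int = 0,
    duration_min: Optional[float] = None,
    cfg: TrimpConfig = TrimpConfig(),
    specs: Optional[Sequence[SessionSpec]] = None,
    rr_series: Optional[Sequence[RRSeries]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic modeling dataset via the direct RR path.

    Returns ``(features, targets, manifest)`` indexed by session id.
    ``features`` holds the predictor roster (leakage-audited), ``targets``
    the TRIMP value and tertile stratum, ``manifest`` the session metadata
    used for stratified folds.
    """
    if specs is None:
        specs = cohort_specs(
            n_subjects, sessions_per_subject, seed=seed, duration_min=duration_min
        )
    if rr_series is None:
        rr_series = [generate_rr_series(s) for s in specs]
    feat_rows, target_rows, manifest_rows = [], [], []
    for i, (spec, rr) in enumerate(zip(specs, rr_series)):
        sid = f"{spec.subject_id}_{i:04d}"
        row = session_row(rr, spec)
        row["session_id"] = sid
        feat_rows.append(row)
        target_rows.append({"session_id": sid, "trimp": session_trimp(rr, spec, cfg)})
        manifest_rows.append(
            {
                "session_id": sid,
                "subject_id": spec.subject_id,
                "sex": spec.sex,
                "session_type": spec.session_type,
                "duration_min": spec.duration_min,
                "resting_hr": spec.resting_hr,
                "max_hr": spec.max_hr,
            }
        )
    features = pd.DataFrame(feat_rows).set_index("session_id")
    targets = pd.DataFrame(target_rows).set_index("session_id")
    targets["stratum"] = stratify(targets["trimp"].to_numpy())
    manifest = pd.DataFrame(manifest_rows).set_index("session_id")
    manifest["stratum"] = targets["stratum"]

    audit = leakage_audit(features[FEATURE_COLUMNS], targets["trimp"].to_numpy())
    if set(audit.retained) != set(FEATURE_COLUMNS):
        logger.warning("leakage audit dropped predictors: %s", audit.dropped)
    return features, targets, manifest


def predictor_table(features: pd.DataFrame, target: np.ndarray) -> pd.DataFrame:
    """The leakage-audited predictor roster of a feature table."""
    numeric = features.select_dtypes(include=[np.number])
    audit = leakage_audit(numeric, target)
    return features[audit.retained]
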