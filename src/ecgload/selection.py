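"""Feature selection: mutual-information ranking, VIF filtering, RFE.

Pipeline order is fixed and logged: constant columns out first, then the
iterative variance-inflation-factor filter (threshold 5), then
mutual-information ranking, then recursive feature elimination down to
``n_keep``.  VIF runs before RFE because estimator importances are unstable
under collinearity.  Selection is meant to run inside each cross-validation
training fold only; the per-fold retained sets are reported.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.feature_selection import (
    RFE,
    mutual_info_classif,
    mutual_info_regression,
)

logger = logging.getLogger(__name__)

VIF_THRESHOLD = 5.0
DEFAULT_N_KEEP = 8


@dataclasses.dataclass
class SelectionReport:
    mi_scores: Dict[str, float]
    rfe_ranking: Dict[str, int]
    vif_values: Dict[str, float]
    retained: List[str]
    dropped: Dict[str, str]  # column -> reason in {vif, rfe, constant}


def mutual_information(
    X: pd.DataFrame,
    y: Sequence[float],
    discrete_target: bool = False,
    k: int = 3,
    seed: int = 0,
) -> Tuple[Dict[str, float], List[str]]:
    """k-nearest-neighbour MI estimate per feature (nats, truncated at 0).

    Returns (scores, constant_columns); constant features score 0 and are
    flagged.
    """
    if len(X) < 20:
        raise ValueError("need at least 20 paired observations")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    scores: Dict[str, float] = {c: 0.0 for c in constant}
    live = [c for c in X.columns if c not in constant]
    if live:
        estimator = mutual_info_classif if discrete_target else mutual_info_regression
        vals = estimator(
            X[live].to_numpy(dtype=float),
            np.asarray(y),
            n_neighbors=k,
            random_state=seed,
        )
        scores.update({c: max(float(v), 0.0) for c, v in zip(live, vals)})
    return scores, constant


def _vif(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) from regressing column j on the others."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.delete(X, j, axis=1), np.ones(n)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(
    X: pd.DataFrame, threshold: float = VIF_THRESHOLD
) -> Tuple[List[str], Dict[str, float], Dict[str, str]]:
    """Iteratively drop the worst feature with VIF above ``threshold``.

    One feature per pass (the largest VIF; ties break to the later-listed
    column, so a duplicated column loses its second copy first), until all
    remaining VIFs are at or below the threshold.
    """
    if len(X) <= X.shape[1]:
        raise ValueError("need more rows than columns for VIF estimation")
    for c in X.columns:
        if X[c].nunique() <= 1:
            raise ValueError(f"constant column {c!r}: remove before VIF filtering")
    cols = list(X.columns)
    dropped: Dict[str, str] = {}
    final_vifs: Dict[str, float] = {}
    while len(cols) > 1:
        vifs = _vif(X[cols].to_numpy(dtype=float))
        final_vifs = {c: float(v) for c, v in zip(cols, vifs)}
        worst = np.max(vifs)
        if worst <= threshold:
            break
        # later-listed column wins the tie for removal
        candidates = np.flatnonzero(
            np.isinf(vifs) if np.isinf(worst) else vifs == worst
        )
        victim = cols[int(candidates[-1])]
        dropped[victim] = "vif"
        cols.remove(victim)
    return cols, final_vifs, dropped


def rfe(
    X: pd.DataFrame,
    y: Sequence[float],
    n_keep: int = DEFAULT_N_KEEP,
    estimator=None,
    discrete_target: bool = False,
    seed: int = 0,
) -> Tuple[List[str], Dict[str, int]]:
    """Recursive feature elimination: drop the least important feature per fit.

    The ranking records drop order (1 = kept longest / retained).
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if n_keep > X.shape[1]:
        raise ValueError("n_keep exceeds the number of features")
    if n_keep == X.shape[1]:
        return list(X.columns), {c: 1 for c in X.columns}
    if estimator is None:
        cls = RandomForestClassifier if discrete_target else RandomForestRegressor
        estimator = cls(n_estimators=200, random_state=seed)
    selector = RFE(estimator, n_features_to_select=n_keep, step=1)
    selector.fit(X.to_numpy(dtype=float), np.asarray(y))
    ranking = {c: int(r) for c, r in zip(X.columns, selector.ranking_)}
    retained = [c for c in X.columns if ranking[c] == 1]
    return retained, ranking


def select_features(
    X: pd.DataFrame,
    y: Sequence[float],
    n_keep: int = DEFAULT_N_KEEP,
    vif_threshold: float = VIF_THRESHOLD,
    discrete_target: bool = False,
    seed: int = 0,
) -> SelectionReport:
    """Full selection pass: constants -> VIF -> MI ranking -> RFE."""
    dropped: Dict[str, str] = {}
    live = []
    for c in X.columns:
        if X[c].nunique() <= 1:
            dropped[c] = "constant"
        else:
            live.append(c)
    logger.info("selection order: constants -> VIF -> MI -> RFE")
    cols, vifs, vif_dropped = vif_filter(X[live], threshold=vif_threshold)
    dropped.update(vif_dropped)
    mi_scores, _ = mutual_information(
        X[cols], y, discrete_target=discrete_target, seed=seed
    )
    n_keep = min(n_keep, len(cols))
    retained, ranking = rfe(
        X[cols], y, n_keep=n_keep, discrete_target=discrete_target, seed=seed
    )
    for c in cols:
        if c not in retained:
            dropped[c] = "rfe"
    return SelectionReport(
        mi_scores=mi_scores,
        rfe_ranking=ranking,
        vif_values=vifs,
        retained=retained,
        dropped=dropped,
    )
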