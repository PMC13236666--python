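"""Summary tables: group contrasts, descriptive statistics, benchmark deltas.

Percent changes are rounded half-away-from-zero at one decimal, matching
the convention of printed load-monitoring tables; mean +/- SD summaries use
the sample SD (n-1).
"""

from __future__ import annotations

import dataclasses
import json
import math
import platform
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 0.05 -> 0.1 and -0.05 -> -0.1)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def pct_change(mean_a: float, mean_b: float) -> Optional[float]:
    """100 * (b - a) / a, one-decimal rounding; missing when a is zero."""
    if mean_a == 0:
        return None
    return round_half_away(100.0 * (mean_b - mean_a) / mean_a)


def improvement_over_benchmark(auc_model: float, auc_benchmark: float) -> float:
    """Relative AUC improvement over a benchmark, percent at one decimal."""
    if auc_benchmark <= 0:
        raise ValueError("benchmark AUC must be positive")
    return round_half_away(100.0 * (auc_model - auc_benchmark) / auc_benchmark)


@dataclasses.dataclass
class ContrastRow:
    metric: str
    unit: str
    mean_a: float
    sd_a: Optional[float]
    mean_b: float
    sd_b: Optional[float]
    pct_change: Optional[float]


def describe_cohort(
    table: pd.DataFrame,
    group_col: str,
    value_cols: Sequence[str],
    group_a: str,
    group_b: str,
    units: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-group mean +/- sample SD with a percent-change contrast column."""
    units = units or {}
    rows = []
    for col in value_cols:
        a = table.loc[table[group_col] == group_a, col].dropna()
        b = table.loc[table[group_col] == group_b, col].dropna()
        if len(a) < 2 or len(b) < 2:
            sd_a = float(a.std(ddof=1)) if len(a) > 1 else None
            sd_b = float(b.std(ddof=1)) if len(b) > 1 else None
        else:
            sd_a, sd_b = float(a.std(ddof=1)), float(b.std(ddof=1))
        row = ContrastRow(
            metric=col,
            unit=units.get(col, ""),
            mean_a=float(a.mean()),
            sd_a=sd_a,
            mean_b=float(b.mean()),
            sd_b=sd_b,
            pct_change=pct_change(float(a.mean()), float(b.mean())),
        )
        rows.append(dataclasses.asdict(row))
    return pd.DataFrame(rows).set_index("metric")


def contrast_markdown(contrast: pd.DataFrame, group_a: str, group_b: str) -> str:
    """Render a contrast table as GitHub-style markdown."""
    lines = [
        f"| Metric | Unit | {group_a} (mean ± SD) | {group_b} (mean ± SD) | % change |",
        "|---|---|---|---|---|",
    ]
    for metric, row in contrast.iterrows():
        def fmt(mean, sd):
            if sd is None or (isinstance(sd, float) and math.isnan(sd)):
                return f"{mean:.2f}"
            return f"{mean:.2f} ± {sd:.2f}"
        pc = "—" if row["pct_change"] is None else f"{row['pct_change']:+.1f}"
        lines.append(
            f"| {metric} | {row['unit']} | {fmt(row['mean_a'], row['sd_a'])} "
            f"| {fmt(row['mean_b'], row['sd_b'])} | {pc} |"
        )
    return "\n".join(lines)


def cv_summary_table(report) -> pd.DataFrame:
    """Mean +/- SD per metric per model from a CvReport."""
    rows = []
    for name, metrics in report.aggregate.items():
        row = {"model": name}
        for metric, (mean, sd) in metrics.items():
            row[metric] = mean
            row[f"{metric}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


def provenance(seed: int, config: Optional[dict] = None) -> dict:
    """Run-level provenance block: seed, configuration, library versions."""
    import scipy
    import sklearn
    import xgboost

    return {
        "seed": seed,
        "config": config or {},
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
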