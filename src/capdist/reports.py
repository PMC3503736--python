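"""Deterministic, bit-stable TSV report writers.

Minutes are rendered at 2 decimals and Gini coefficients at 3 decimals in
reports only; all upstream statistics are computed at full precision.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import AssignmentResult, GapTable, LoadSummary
from .equity import TimeSummary, gini, summarize_times
from .scenarios import ScenarioResult

__all__ = [
    "commuting_time_report",
    "gap_report",
    "scenario_report",
    "load_report",
    "write_assignment_csv",
    "write_lorenz_csv",
]


def _fmt_min(v: float) -> str:
    return f"{v:.2f}"


def commuting_time_report(
    results: Mapping[str, AssignmentResult],
    strata: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Stratified commuting-time table: per model and stratum, n, median,
    IQR, range (2-decimal minutes) and Gini (3 decimals)."""
    rows = []
    for model_name, res in results.items():
        times = res.time.to_numpy(dtype=float)
        groups: list[tuple[str, np.ndarray]] = [("whole", times)]
        if strata is not None:
            labels = res.table.index.map(strata)
            for s in sorted(set(labels)):
                groups.append((s, times[labels == s]))
        for stratum, t in groups:
            ts = summarize_times(t)
            rows.append(
                {
                    "model": model_name,
                    "stratum": stratum,
                    "n": ts.n,
                    "median_min": _fmt_min(ts.median),
                    "iqr_min": f"{_fmt_min(ts.q25)}-{_fmt_min(ts.q75)}",
                    "min_min": _fmt_min(ts.min),
                    "max_min": _fmt_min(ts.max),
                    "gini": f"{gini(t):.3f}",
                }
            )
    return pd.DataFrame(rows)


def gap_report(gaps: GapTable) -> pd.DataFrame:
    """Per-proximity-rank gap table with a trailing share line."""
    df = gaps.table.reset_index()
    out = pd.DataFrame(
        {
            "rank": df["rank"].astype(str),
            "n": df["n"].astype(str),
            "gap_median_min": df["gap_median"].map(_fmt_min),
            "gap_iqr_min": [
                f"{_fmt_min(a)}-{_fmt_min(b)}"
                for a, b in zip(df["gap_q25"], df["gap_q75"])
            ],
        }
    )
    share = 100.0 * gaps.share_non_nearest
    out.loc[len(out)] = ["non-nearest", str(gaps.n_non_nearest), f"{share:.1f}%", ""]
    return out


def scenario_report(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Scenario table: capacity delta, Gini, n patients and threshold
    counts per row; infeasible scenarios carry the error text."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "scenario": r.name,
            "capacity_delta": f"{r.capacity_delta:+d}" if r.capacity_delta else "0",
        }
        if r.ok:
            row["gini"] = f"{r.gini:.3f}"
            row["n"] = r.summary_overall.n
            for th, c in r.threshold_counts.items():
                row[f">{th:g}"] = c
        else:
            row["gini"] = "error"
            row["n"] = r.error
        rows.append(row)
    return pd.DataFrame(rows)


def load_report(summary: LoadSummary) -> pd.DataFrame:
    """Aggregate facility-load accounting under nearest-facility demand."""
    return pd.DataFrame(
        [
            {
                "group": "overloaded",
                "n_facilities": summary.n_overloaded,
                "group_capacity": summary.overloaded_capacity,
                "median": summary.excess_median,
                "range": f"{summary.excess_range[0]}-{summary.excess_range[1]}",
                "total": summary.excess_total,
            },
            {
                "group": "underloaded",
                "n_facilities": summary.n_underloaded,
                "group_capacity": summary.underloaded_capacity,
                "median": summary.slack_median,
                "range": f"{summary.slack_range[0]}-{summary.slack_range[1]}",
                "total": summary.slack_total,
            },
        ]
    )


def write_assignment_csv(result: AssignmentResult, path) -> None:
    """Full-precision per-patient assignment CSV."""
    df = result.table.copy()
    df["model"] = result.model
    df.to_csv(path, index=True)


def write_lorenz_csv(curve, path) -> None:
    """Lorenz polyline as (cum_patient_share, cum_time_share) CSV."""
    pd.DataFrame(
        curve.points, columns=["cum_patient_share", "cum_time_share"]
    ).to_csv(path, index=False)
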