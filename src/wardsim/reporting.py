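"""Replication aggregation and table rendering.

Outcome rates are patient-shift weighted: every patient present on an
understaffed ward-shift counts toward the understaffed percentage.  Cross-
replication means carry t-based 95% confidence intervals (replication counts
are small).  Whole-sample rows in rendered tables weight hospitals by
patient shifts, not by averaging hospital percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costing import CostBreakdown
from .demand import GROUPS

SOURCES = ("permanent", "redeployed", "bank", "agency")

_SOURCE_COLUMNS = {
    "permanent": [f"perm_{g}" for g in GROUPS],
    "redeployed": [f"redeployed_in_{g}" for g in GROUPS],
    "bank": [f"bank_{g}" for g in GROUPS],
    "agency": [f"agency_{g}" for g in GROUPS],
}

METRICS = (
    "pct_understaffed",
    "pct_overstaffed",
    "cost_per_patient_day",
    "permanent_cost",
    "total_cost",
) + tuple(f"pct_hours_{s}" for s in SOURCES)


@dataclass(frozen=True)
class ReplicationMetrics:
    """Outcome measures for a single simulated year."""

    patient_shifts: int
    pct_understaffed: float
    pct_overstaffed: float
    pct_hours_by_source: Mapping[str, float]
    cost_per_patient_day: float
    total_cost: float
    permanent_cost: float

    def metric(self, name: str) -> float:
        if name.startswith("pct_hours_"):
            return self.pct_hours_by_source[name[len("pct_hours_"):]]
        return getattr(self, name)


@dataclass(frozen=True)
class RunSummary:
    """Cross-replication means with 95% CI halfwidths."""

    n_replications: int
    patient_shifts: float
    means: Mapping[str, float]
    ci95_halfwidth: Mapping[str, float | None]


def summarize_replication(
    records: pd.DataFrame, costs: CostBreakdown
) -> ReplicationMetrics:
    """Reduce one year of ward-shift records to outcome metrics."""
    if records.empty:
        raise ValueError("record stream is empty")
    patients = records["patients"].to_numpy(dtype=np.float64)
    total_patient_shifts = patients.sum()
    if total_patient_shifts <= 0:
        raise ValueError("no patient shifts in record stream")
    state = records["state"].to_numpy()
    pct_under = 100.0 * patients[state == "understaffed"].sum() / total_patient_shifts
    pct_over = 100.0 * patients[state == "overstaffed"].sum() / total_patient_shifts

    raw_hours = {
        src: float(sum(records[c].sum() for c in cols))
        for src, cols in _SOURCE_COLUMNS.items()
    }
    total_raw = sum(raw_hours.values())
    shares = {
        src: (100.0 * h / total_raw if total_raw > 0 else 0.0)
        for src, h in raw_hours.items()
    }
    return ReplicationMetrics(
        patient_shifts=int(total_patient_shifts),
        pct_understaffed=float(pct_under),
        pct_overstaffed=float(pct_over),
        pct_hours_by_source=shares,
        cost_per_patient_day=costs.cost_per_patient_day,
        total_cost=costs.total_cost,
        permanent_cost=costs.permanent_cost,
    )


def aggregate_replications(
    metrics: Sequence[ReplicationMetrics],
) -> RunSummary:
    """Mean across replications; 95% CI halfwidth = t(n-1, .975) x sd / sqrt(n).

    With a single replication the mean is reported and every CI halfwidth is
    flagged unavailable (None).
    """
    n = len(metrics)
    if n == 0:
        raise ValueError("need at least one replication")
    means: dict[str, float] = {}
    ci: dict[str, float | None] = {}
    for name in METRICS:
        vals = np.array([m.metric(name) for m in metrics], dtype=np.float64)
        means[name] = float(vals.mean())
        if n >= 2:
            hw = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / math.sqrt(n)
            ci[name] = float(hw)
        else:
            ci[name] = None
    return RunSummary(
        n_replications=n,
        patient_shifts=float(np.mean([m.patient_shifts for m in metrics])),
        means=means,
        ci95_halfwidth=ci,
    )


def correlation_under_over(
    pct_understaffed: Sequence[float], pct_overstaffed: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of ward-level understaffing vs overstaffing.

    Returns (r, p).  Constant input makes the coefficient undefined; the
    result is flagged as (nan, nan).
    """
    u = np.asarray(pct_understaffed, dtype=np.float64)
    o = np.asarray(pct_overstaffed, dtype=np.float64)
    if u.size != o.size:
        raise ValueError("input vectors differ in length")
    if u.size < 3:
        raise ValueError("need at least 3 wards")
    if np.ptp(u) == 0 or np.ptp(o) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(u, o)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# table rendering
# ---------------------------------------------------------------------------

TABLE_COLUMNS = (
    "scenario",
    "policy",
    "hospital",
    "patient_shifts",
    "pct_understaffed",
    "pct_overstaffed",
    "cost_per_patient_day",
)


def grid_table(
    summaries: Mapping[tuple[str, str], Mapping[str, RunSummary]]
) -> pd.DataFrame:
    """Tidy table over a (scenario, policy) grid with per-hospital rows plus
    a patient-shift-weighted "Whole sample" row per grid cell."""
    rows = []
    for (scenario, policy), by_hospital in sorted(summaries.items()):
        weights = []
        for hospital_id in sorted(by_hospital):
            s = by_hospital[hospital_id]
            rows.append(
                {
                    "scenario": scenario,
                    "policy": policy,
                    "hospital": hospital_id,
                    "patient_shifts": s.patient_shifts,
                    "pct_understaffed": s.means["pct_understaffed"],
                    "pct_overstaffed": s.means["pct_overstaffed"],
                    "cost_per_patient_day": s.means["cost_per_patient_day"],
                }
            )
            weights.append(s.patient_shifts)
        total = sum(weights)
        if total > 0:
            whole = {
                "scenario": scenario,
                "policy": policy,
                "hospital": "Whole sample",
                "patient_shifts": total,
            }
            for col in ("pct_understaffed", "pct_overstaffed"):
                whole[col] = (
                    sum(
                        by_hospital[h].patient_shifts * by_hospital[h].means[col]
                        for h in by_hospital
                    )
                    / total
                )
            # costs combine as total cost over total patient-days
            total_days = sum(
                by_hospital[h].patient_shifts / 4.0 for h in by_hospital
            )
            whole["cost_per_patient_day"] = (
                sum(
                    by_hospital[h].means["cost_per_patient_day"]
                    * by_hospital[h].patient_shifts
                    / 4.0
                    for h in by_hospital
                )
                / total_days
            )
            rows.append(whole)
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def to_markdown(frame: pd.DataFrame, floatfmt: str = ".2f") -> str:
    """Minimal GitHub-flavoured markdown table (no tabulate dependency)."""
    def fmt(v):
        if isinstance(v, float):
            return format(v, floatfmt)
        return str(v)

    headers = [str(c) for c in frame.columns]
    lines = ["| " + " | ".join(headers) + " |"]
    lines.append("| " + " | ".join("---" for _ in headers) + " |")
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def render_tables(
    summaries: Mapping[tuple[str, str], Mapping[str, RunSummary]],
    out_csv=None,
    out_markdown=None,
) -> pd.DataFrame:
    """Render the grid table; optionally write CSV and markdown files."""
    frame = grid_table(summaries)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    if out_markdown is not None:
        with open(out_markdown, "w") as fh:
            fh.write(to_markdown(frame))
    return frame
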