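"""Temporal properties of brain-state sequences.

Given each subject's per-window state assignments (values 1..k), three
summaries describe how the subject moves through connectivity states:

* fraction of time (occupancy) — share of windows spent in each state;
* mean dwell time — average length, in windows, of contiguous runs of a
  state (states never visited contribute 0 under the default policy);
* transition number — count of window-to-window state changes.

Dwell times are reported in windows; multiply by TR x window step for
seconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import GroupTestResult, bh_fdr, two_sample_t
from .types import TemporalMetrics

__all__ = [
    "fraction_of_time", "mean_dwell_time", "n_transitions",
    "compute_metrics", "metrics_frame", "metrics_group_contrast",
]


def _check_assignments(assignments, k: int) -> np.ndarray:
    a = np.asarray(assignments, dtype=int)
    if a.size == 0:
        raise ValueError("empty state sequence")
    if a.min() < 1 or a.max() > k:
        raise ValueError(f"assignment values must lie in 1..{k}")
    return a


def fraction_of_time(assignments, k: int) -> np.ndarray:
    """Proportion of windows assigned to each state 1..k."""
    a = _check_assignments(assignments, k)
    return np.bincount(a, minlength=k + 1)[1:] / a.size


def mean_dwell_time(assignments, k: int, absent_policy: str = "zero") -> np.ndarray:
    """Mean contiguous run length per state, in windows.

    States never visited get 0 under ``absent_policy="zero"`` or NaN under
    ``"nan"``.
    """
    if absent_policy not in ("zero", "nan"):
        raise ValueError(f"unknown absent_policy: {absent_policy!r}")
    a = _check_assignments(assignments, k)
    # run-length encode: boundaries where the state changes
    change = np.flatnonzero(np.diff(a)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [a.size]]))
    run_states = a[starts]
    out = np.full(k, 0.0 if absent_policy == "zero" else np.nan)
    for j in range(1, k + 1):
        runs = lengths[run_states == j]
        if runs.size:
            out[j - 1] = runs.mean()
    return out


def n_transitions(assignments) -> int:
    """Number of positions where the state differs from the previous window."""
    a = np.asarray(assignments, dtype=int)
    if a.size == 0:
        raise ValueError("empty state sequence")
    return int(np.count_nonzero(np.diff(a)))


def compute_metrics(subject_id: str, assignments, k: int,
                    absent_policy: str = "zero") -> TemporalMetrics:
    """Bundle all three temporal metrics for one subject."""
    return TemporalMetrics(
        subject_id=subject_id,
        fraction_of_time=fraction_of_time(assignments, k),
        mean_dwell=mean_dwell_time(assignments, k, absent_policy),
        n_transitions=n_transitions(assignments),
    )


def metrics_frame(metrics: list[TemporalMetrics]) -> pd.DataFrame:
    """Long-to-wide table: one row per subject, one column per metric."""
    rows = []
    for m in metrics:
        k = m.fraction_of_time.size
        row: dict = {"subject_id": m.subject_id, "n_transitions": m.n_transitions}
        for j in range(k):
            row[f"fraction_state{j + 1}"] = m.fraction_of_time[j]
            row[f"dwell_state{j + 1}"] = m.mean_dwell[j]
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_group_contrast(metrics: list[TemporalMetrics],
                           clinical: pd.DataFrame,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Pooled two-sample t per temporal metric (2k+1 tests).

    Returns a frame shaped like a demographics-style summary table: one row
    per metric with patient / control mean +- SD, t, df, p, and BH-FDR
    adjusted p across the 2k+1 tests.
    """
    wide = metrics_frame(metrics).merge(
        clinical[["subject_id", "group"]], on="subject_id", validate="1:1")
    pat = wide[wide["group"] == "PACG"]
    ctl = wide[wide["group"] == "HC"]
    if len(pat) < 2 or len(ctl) < 2:
        raise ValueError("each group needs at least 2 subjects")
    k = sum(c.startswith("fraction_state") for c in wide.columns)
    units = ["n_transitions"]
    for j in range(1, k + 1):
        units += [f"fraction_state{j}", f"dwell_state{j}"]
    rows = []
    for unit in units:
        t, df, p = two_sample_t(pat[unit].to_numpy(), ctl[unit].to_numpy())
        rows.append({
            "metric": unit,
            "patient_mean": pat[unit].mean(), "patient_sd": pat[unit].std(ddof=1),
            "control_mean": ctl[unit].mean(), "control_sd": ctl[unit].std(ddof=1),
            "t": t, "df": df, "p": p,
        })
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["p_fdr"] < alpha
    return out


def group_test_results(contrast: pd.DataFrame) -> list[GroupTestResult]:
    """Convert a contrast frame into GroupTestResult records."""
    return [
        GroupTestResult(
            unit_label=row["metric"],
            estimate=row["patient_mean"] - row["control_mean"],
            t_stat=row["t"], df=int(row["df"]), p=row["p"],
            p_fdr=row["p_fdr"], significant=bool(row["significant"]),
        )
        for _, row in contrast.iterrows()
    ]
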