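"""Per-subject temporal dynamics of decoded states.

Four measures per (subject, state), computed on the binary one-hot state
time-courses within each subject's segment:

- fractional occupancy: percentage of the subject's samples the state is
  active (sums to 100 % over states);
- number of occurrences: count of maximal contiguous visits;
- mean lifetime: average visit duration, reported in milliseconds;
- mean interval: average gap from the end of one visit to the start of the
  next, reported in seconds.

Lifetimes and intervals are undefined (NaN, never zero) when a state has no
visits, or fewer than two visits respectively; group summaries exclude
undefined values pairwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmm import StateTimeCourses

__all__ = [
    "MEASURES",
    "find_runs",
    "subject_state_metrics",
    "compute_metrics",
    "group_summary",
    "difference_of_means",
]

MEASURES = ("fractional_occupancy", "n_occurrences", "mean_lifetime", "mean_interval")

# tidy-table column per measure, with reporting units baked into the name
MEASURE_COLUMNS = {
    "fractional_occupancy": "fractional_occupancy",  # percent
    "n_occurrences": "n_occurrences",  # count
    "mean_lifetime": "mean_lifetime_ms",  # milliseconds
    "mean_interval": "mean_interval_s",  # seconds
}


def find_runs(binary_sequence: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of ones as (onset, length), 0-based half-open."""
    seq = np.asarray(binary_sequence)
    if seq.size and not np.all(np.isin(seq, (0, 1))):
        raise ValueError("sequence must be binary")
    padded = np.concatenate([[0], seq, [0]])
    d = np.diff(padded)
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1)
    return [(int(on), int(off - on)) for on, off in zip(onsets, offsets)]


def subject_state_metrics(
    activations: np.ndarray, sampling_rate: float, subject_id: str = "subject-0"
) -> pd.DataFrame:
    """Metrics for one subject's K x T one-hot activation block."""
    act = np.asarray(activations)
    if act.ndim != 2 or act.shape[1] == 0:
        raise ValueError("empty or malformed segment")
    if not np.array_equal(act.sum(axis=0), np.ones(act.shape[1])):
        raise ValueError("segment columns must be one-hot")
    K, T = act.shape
    rows = []
    for k in range(K):
        runs = find_runs(act[k])
        active = int(act[k].sum())
        fo = 100.0 * active / T
        n_occ = len(runs)
        lifetime_ms = (
            1000.0 * float(np.mean([length for _, length in runs])) / sampling_rate
            if runs
            else np.nan
        )
        if n_occ >= 2:
            gaps = [
                runs[i + 1][0] - (runs[i][0] + runs[i][1]) for i in range(n_occ - 1)
            ]
            interval_s = float(np.mean(gaps)) / sampling_rate
        else:
            interval_s = np.nan
        rows.append(
            {
                "subject_id": subject_id,
                "state": k,
                "fractional_occupancy": fo,
                "n_occurrences": n_occ,
                "mean_lifetime_ms": lifetime_ms,
                "mean_interval_s": interval_s,
            }
        )
    return pd.DataFrame(rows)


def compute_metrics(stc: StateTimeCourses, sampling_rate: float) -> pd.DataFrame:
    """Tidy per-(subject, state) metrics table over all subject segments."""
    frames = [
        subject_state_metrics(stc.activations[:, s:e], sampling_rate, sid)
        for sid, s, e in stc.subject_boundaries
    ]
    return pd.concat(frames, ignore_index=True)


def group_summary(
    metrics_table: pd.DataFrame,
    group_labels: dict[str, str],
    control: str = "A",
    case: str = "B",
) -> pd.DataFrame:
    """Per-group, per-state mean and SD of all four measures, plus the
    control-minus-case difference of group means.

    Undefined (NaN) per-subject values are excluded pairwise. Single-subject
    groups yield NaN SDs (flagged undefined, sample SD needs n >= 2).
    """
    table = metrics_table.copy()
    unknown = set(table["subject_id"]) - set(group_labels)
    if unknown:
        raise ValueError(f"subjects without group label: {sorted(unknown)}")
    table["group"] = table["subject_id"].map(group_labels)
    bad = set(table["group"]) - {control, case}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")

    rows = []
    for state, chunk in table.groupby("state"):
        row: dict = {"state": state}
        for measure, col in MEASURE_COLUMNS.items():
            a = chunk.loc[chunk["group"] == control, col].dropna()
            b = chunk.loc[chunk["group"] == case, col].dropna()
            row[f"{measure}_mean_{control}"] = a.mean() if len(a) else np.nan
            row[f"{measure}_sd_{control}"] = a.std(ddof=1) if len(a) >= 2 else np.nan
            row[f"{measure}_mean_{case}"] = b.mean() if len(b) else np.nan
            row[f"{measure}_sd_{case}"] = b.std(ddof=1) if len(b) >= 2 else np.nan
            row[f"{measure}_diff"] = difference_of_means(
                row[f"{measure}_mean_{control}"], row[f"{measure}_mean_{case}"]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def difference_of_means(control_mean: float, case_mean: float) -> float:
    """Control-minus-case difference of group means (the sign convention used
    throughout the group comparison)."""
    return control_mean - case_mean
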