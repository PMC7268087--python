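"""Permutation-based two-group comparison with BH-FDR control.

For each (state, measure) the observed control-minus-case difference of
group means is compared to a null built by relabelling the pooled
per-subject values into groups of the original sizes (default 10,000
relabellings). The two-sided p uses the add-one estimator
``p = (1 + #{|null| >= |observed|}) / (n_permutations + 1)``, which is a
valid p-value under finite permutations and never returns zero. P-values
across the family of tests are corrected with the Benjamini-Hochberg
step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .metrics import MEASURE_COLUMNS, MEASURES

__all__ = [
    "PermutationResult",
    "permutation_test",
    "exhaustive_permutation_test",
    "bh_fdr",
    "compare_all",
]


@dataclass
class PermutationResult:
    observed_difference: float
    p_value: float
    n_permutations: int
    seed: int | None
    null_mean: float
    null_quantiles: dict[float, float]
    degenerate: bool = False


def permutation_test(
    values_a,
    values_b,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> PermutationResult:
    """Two-sided group-relabelling test of the difference of means (A - B).

    NaN values (undefined metrics for a subject) are dropped before pooling.
    If every pooled value is identical the test is degenerate and p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pooled = np.concatenate([a, b])
    observed = a.mean() - b.mean()
    if np.ptp(pooled) == 0:
        return PermutationResult(observed, 1.0, n_permutations, seed, 0.0, {}, degenerate=True)

    rng = np.random.default_rng(seed)
    n, n_a = pooled.size, a.size
    # each row of `order` is a random relabelling; first n_a entries -> group A
    null = np.empty(n_permutations)
    chunk = max(1, int(5e6) // n)
    total = pooled.sum()
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        order = np.argsort(rng.random((m, n)), axis=1)
        sums_a = pooled[order[:, :n_a]].sum(axis=1)
        null[done : done + m] = sums_a / n_a - (total - sums_a) / (n - n_a)
        done += m
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed) - 1e-12)) / (n_permutations + 1.0)
    qs = {q: float(np.quantile(null, q)) for q in (0.025, 0.5, 0.975)}
    return PermutationResult(float(observed), float(p), n_permutations, seed, float(null.mean()), qs)


def exhaustive_permutation_test(values_a, values_b) -> float:
    """Exact two-sided p over all C(n_a + n_b, n_a) group assignments.

    The null includes the observed assignment, so p >= 1 / n_assignments.
    Refuses combinatorially infeasible inputs (> 1e6 assignments).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    from math import comb

    n, n_a = a.size + b.size, a.size
    if comb(n, n_a) > 1_000_000:
        raise ValueError("too many assignments for exhaustive enumeration")
    pooled = np.concatenate([a, b])
    observed = a.mean() - b.mean()
    total = pooled.sum()
    count = 0
    n_assign = 0
    for idx in combinations(range(n), n_a):
        sa = pooled[list(idx)].sum()
        diff = sa / n_a - (total - sa) / (n - n_a)
        if abs(diff) >= abs(observed) - 1e-12:
            count += 1
        n_assign += 1
    return count / n_assign


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def compare_all(
    metrics_table: pd.DataFrame,
    group_labels: dict[str, str],
    measures=MEASURES,
    n_permutations: int = 10_000,
    seed: int | None = 0,
    q: float = 0.05,
    control: str = "A",
    case: str = "B",
    family: str = "all",
) -> pd.DataFrame:
    """Per-(state, measure) permutation tests with BH-FDR correction.

    ``family='all'`` corrects across every state x measure test jointly (the
    default, 32 tests for 8 states x 4 measures); ``family='per_measure'``
    corrects within each measure separately.
    """
    if family not in ("all", "per_measure"):
        raise ValueError("family must be 'all' or 'per_measure'")
    table = metrics_table.copy()
    table["group"] = table["subject_id"].map(group_labels)
    if table["group"].isna().any():
        raise ValueError("every subject needs a group label")
    counts = table.groupby("group")["subject_id"].nunique()
    if counts.get(control, 0) < 2 or counts.get(case, 0) < 2:
        raise ValueError("need at least two subjects per group")

    root = np.random.default_rng(seed)
    rows = []
    for state in sorted(table["state"].unique()):
        chunk = table[table["state"] == state]
        for measure in measures:
            col = MEASURE_COLUMNS[measure]
            res = permutation_test(
                chunk.loc[chunk["group"] == control, col],
                chunk.loc[chunk["group"] == case, col],
                n_permutations=n_permutations,
                seed=int(root.integers(2**31)),
            )
            rows.append(
                {
                    "state": state,
                    "measure": measure,
                    "observed_diff": res.observed_difference,
                    "p": res.p_value,
                    "degenerate": res.degenerate,
                }
            )
    report = pd.DataFrame(rows)
    if family == "all":
        adj, rej = bh_fdr(report["p"].to_numpy(), q)
        report["p_adjusted"], report["significant"] = adj, rej
    else:
        report["p_adjusted"] = np.nan
        report["significant"] = False
        for measure in measures:
            mask = report["measure"] == measure
            adj, rej = bh_fdr(report.loc[mask, "p"].to_numpy(), q)
            report.loc[mask, "p_adjusted"] = adj
            report.loc[mask, "significant"] = rej
    return report
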