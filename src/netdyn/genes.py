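"""Association between state spatial maps and regional gene expression.

Each state's spatial map (partial correlations over analysis parcels) is
projected onto 68 cortical regions (34 per hemisphere, Desikan-Killiany
naming convention), the 20 most active regions are selected by absolute
partial correlation, and the gene-expression values of those regions are
summed. The score is compared against a null of 10,000 random 20-of-68
subsets (one-sided, upper tail: the question is whether expression in a
network is elevated relative to chance). Across states, the per-state
expression p-values are rank-correlated (Spearman) with the per-state
group-difference p-values of each temporal measure; both p-vectors index
effect magnitude, so a positive rho means networks with stronger group
effects carry higher expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DK_REGIONS",
    "ExpressionMap",
    "ParcelRegionProjection",
    "identity_projection",
    "uniform_overlap_projection",
    "project_state_map",
    "state_expression_score",
    "null_scores",
    "expression_pvalue",
    "spearman_association",
    "association_report",
]

# the 34 cortical region names of the standard surface-based anatomical
# parcellation, mirrored over hemispheres for the 68-region convention
_DK_BASE = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
]
DK_REGIONS = [f"lh-{r}" for r in _DK_BASE] + [f"rh-{r}" for r in _DK_BASE]


@dataclass
class ExpressionMap:
    """68 labelled regional expression values (arbitrary microarray units)."""

    region_labels: list[str]
    expression: np.ndarray

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if len(self.region_labels) != 68 or self.expression.shape != (68,):
            raise ValueError("an ExpressionMap holds exactly 68 labelled values")
        if len(set(self.region_labels)) != 68:
            raise ValueError("region labels must be unique")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression values must be finite")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpressionMap":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].tolist(), df.iloc[:, 1].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"region_label": self.region_labels, "expression": self.expression}
        ).to_csv(path, index=False)


@dataclass
class ParcelRegionProjection:
    """Non-negative overlap weights mapping P analysis parcels to 68 regions.

    The mapping from an analysis parcellation to the anatomical expression
    regions is made explicit (and swappable) rather than implicit: each
    parcel row must carry positive total weight; regions reachable from no
    parcel are reported by :meth:`unmapped_regions` and surface as NaN after
    projection.
    """

    weights: np.ndarray  # (P, 68)
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 68:
            raise ValueError("weights must be P x 68")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        empty = np.flatnonzero(self.weights.sum(axis=1) == 0)
        if empty.size:
            raise ValueError(f"parcel rows with zero total weight: {empty.tolist()}")

    def unmapped_regions(self) -> list[str]:
        mask = self.weights.sum(axis=0) == 0
        return [lbl for lbl, m in zip(self.region_labels, mask) if m]


def identity_projection(region_labels: list[str] | None = None) -> ParcelRegionProjection:
    """One-to-one projection for runs whose parcellation is the 68 regions."""
    labels = list(region_labels) if region_labels is not None else list(DK_REGIONS)
    return ParcelRegionProjection(np.eye(68), labels)


def uniform_overlap_projection(
    n_parcels: int, region_labels: list[str] | None = None
) -> ParcelRegionProjection:
    """Interval-overlap projection from P parcels to the 68 regions.

    Both parcellations are laid out as equal subdivisions of the unit
    interval; the weight of (parcel, region) is the length of their overlap.
    A neutral, auditable stand-in for an anatomical overlap matrix: it
    degenerates to the identity at P = 68 and spreads each of P < 68 parcels
    over the regions it covers.
    """
    if n_parcels < 1:
        raise ValueError("n_parcels must be >= 1")
    labels = list(region_labels) if region_labels is not None else list(DK_REGIONS)
    W = np.zeros((n_parcels, 68))
    for p in range(n_parcels):
        lo, hi = p / n_parcels, (p + 1) / n_parcels
        for r in range(68):
            rlo, rhi = r / 68.0, (r + 1) / 68.0
            W[p, r] = max(0.0, min(hi, rhi) - max(lo, rlo))
    return ParcelRegionProjection(W, labels)


def project_state_map(
    state_map_over_parcels: np.ndarray, projection: ParcelRegionProjection
) -> np.ndarray:
    """Region activity = per-region weight-normalised average of |map values|.

    The absolute partial correlation is taken before aggregation (a strong
    negative contribution marks a parcel as engaged just as a positive one
    does). Regions with no contributing parcel come out NaN.
    """
    v = np.abs(np.asarray(state_map_over_parcels, dtype=float))
    if v.shape != (projection.weights.shape[0],):
        raise ValueError("state map length does not match projection parcel count")
    W = projection.weights
    totals = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (W.T @ v) / totals
    out[totals == 0] = np.nan
    return out


def state_expression_score(
    region_activity: np.ndarray, expression_map: ExpressionMap, k: int = 20
) -> float:
    """Sum of expression over the k most active regions.

    Ranking is by activity descending; ties at the k-th rank break by fixed
    region-label order, keeping the selection deterministic.
    """
    activity = np.asarray(region_activity, dtype=float)
    if activity.shape != (68,):
        raise ValueError("region activity must have length 68")
    if not 1 <= k <= 68:
        raise ValueError("k must lie in [1, 68]")
    order = sorted(
        range(68),
        key=lambda i: (-(activity[i] if np.isfinite(activity[i]) else -np.inf),
                       expression_map.region_labels[i]),
    )
    top = order[:k]
    return float(expression_map.expression[top].sum())


def null_scores(
    expression_map: ExpressionMap | np.ndarray,
    k: int = 20,
    n_iterations: int = 10_000,
    seed=None,
) -> np.ndarray:
    """Null distribution: sums over uniformly random k-subsets of the
    regions, drawn without replacement.

    Accepts an :class:`ExpressionMap` (the 68-region convention) or a raw
    value vector of any length, which keeps the sampler checkable against
    exhaustive subset enumeration on tiny region sets.
    """
    values = (
        expression_map.expression
        if isinstance(expression_map, ExpressionMap)
        else np.asarray(expression_map, dtype=float)
    )
    n = values.size
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_iterations, n)), axis=1)[:, :k]
    return values[idx].sum(axis=1)


def expression_pvalue(score: float, null: np.ndarray) -> float:
    """One-sided upper-tail p with the add-one estimator; ties count as >=."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float((1 + np.count_nonzero(null >= score - 1e-12)) / (null.size + 1))


def _exact_spearman_pvalue(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho: enumerate all n!
    orderings of one rank vector and count |rho| >= |observed|."""
    n = x_ranks.size
    perms = np.array(list(iter_permutations(range(n))))
    y_perm = y_ranks[perms]  # (n!, n)
    xc = x_ranks - x_ranks.mean()
    yc = y_perm - y_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * np.einsum("ij,ij->i", yc, yc))
    rhos = (yc @ xc) / denom
    return float(np.count_nonzero(np.abs(rhos) >= abs(rho_obs) - 1e-12) / len(perms))


def spearman_association(x, y) -> tuple[float, float]:
    """Spearman rho between two equal-length vectors with an exact
    permutation p for n <= 9 (all n! orderings) and the large-sample
    approximation otherwise. Constant input yields (nan, nan), flagged
    undefined rather than silently zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if x.size <= 9:
        p = _exact_spearman_pvalue(xr, yr, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def association_report(
    expression_pvalues: dict[str, np.ndarray],
    group_report: pd.DataFrame,
    measures=None,
) -> pd.DataFrame:
    """Per (gene, measure) Spearman association between the per-state
    expression p-values and the per-state group-difference p-values.

    ``expression_pvalues`` maps gene name -> length-K vector of per-state
    expression p-values; ``group_report`` is the tidy output of
    :func:`netdyn.groupstats.compare_all`.
    """
    if measures is None:
        measures = sorted(group_report["measure"].unique())
    rows = []
    for gene, expr_p in expression_pvalues.items():
        expr_p = np.asarray(expr_p, dtype=float)
        for measure in measures:
            chunk = group_report[group_report["measure"] == measure].sort_values("state")
            gd_p = chunk["p"].to_numpy()
            if gd_p.size != expr_p.size:
                raise ValueError("state count mismatch between expression and group report")
            rho, p = spearman_association(expr_p, gd_p)
            rows.append({"gene": gene, "measure": measure, "rho": rho, "p": p})
    return pd.DataFrame(rows)
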