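"""Clustering and correlation structure of condition fold-change profiles.

Conditions are (chemical, dose) columns of a genes x condition log2FC matrix.
Hierarchical clustering (default: average linkage on correlation distance
1 - r) groups conditions and genes; pairwise Pearson correlation quantifies
similarity between exposure profiles; the common-gene consensus collects genes
significant at the highest dose of every (or at least k) listed chemicals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "CommonGeneSet",
    "cluster",
    "to_newick",
    "condition_correlation",
    "matthews_condition_correlation",
    "common_genes",
    "pairwise_significant_counts",
]


@dataclass
class ClusterResult:
    """Agglomerative clustering of one axis: scipy linkage matrix, the
    clustered labels, and the deterministic leaf order."""

    linkage: np.ndarray
    labels: list[str]
    axis: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


@dataclass
class CommonGeneSet:
    """Consensus significant genes at the highest dose across chemicals."""

    chemicals: list[str]
    rule: str
    q_threshold: float
    members: list[str]
    per_chemical_sets: dict[str, set[str]] = field(default_factory=dict)


def _label_key(label) -> str:
    return "|".join(map(str, label)) if isinstance(label, tuple) else str(label)


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distances over rows of ``x``; zero-variance
    rows fall back to (normalized) Euclidean distance for their pairs."""
    sd = x.std(axis=1)
    d = pdist(x, metric="correlation") if (sd > 0).all() else None
    if d is not None and np.isfinite(d).all():
        return d
    logger.warning("constant profiles under correlation distance; "
                   "Euclidean fallback for affected pairs")
    n = x.shape[0]
    dm = np.zeros((n, n))
    eu = squareform(pdist(x, metric="euclidean"))
    scale = eu.max() or 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    dm = 1.0 - corr
    bad = ~np.isfinite(dm)
    dm[bad] = (2.0 * eu / scale)[bad]
    np.fill_diagonal(dm, 0.0)
    return squareform(dm, checks=False)


def cluster(
    matrix: pd.DataFrame,
    axis: str = "cols",
    method: str = "average",
    metric: str = "correlation",
) -> ClusterResult | tuple[ClusterResult, ClusterResult]:
    """Hierarchically cluster rows, columns, or both.

    Labels are pre-sorted so that distance ties break deterministically
    regardless of input order.  ``metric`` is any scipy pdist metric;
    ``correlation`` (1 - r) is the default and falls back to Euclidean for
    pairs involving a constant profile.
    """
    if axis not in {"rows", "cols", "both"}:
        raise ValueError(f"unknown axis: {axis}")
    if axis == "both":
        return cluster(matrix, "rows", method, metric), cluster(matrix, "cols", method, metric)
    data = matrix if axis == "rows" else matrix.T
    data = data.loc[sorted(data.index, key=_label_key)]
    if data.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    x = data.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in the matrix")
    d = _correlation_distance(x) if metric == "correlation" else pdist(x, metric=metric)
    z = hierarchy.linkage(d, method=method)
    return ClusterResult(linkage=z, labels=[_label_key(l) for l in data.index], axis=axis)


def to_newick(result: ClusterResult) -> str:
    """Serialize a dendrogram as a Newick string with merge heights as
    branch lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return rec(tree, tree.dist) + ";"


def condition_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between condition columns (unit diagonal;
    zero-variance columns yield NaN against everything else)."""
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    corr = matrix.corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    sd = matrix.std(axis=0)
    dead = sd.index[sd == 0]
    for c in dead:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


def matthews_condition_correlation(
    fc: pd.DataFrame, q: pd.DataFrame, q_threshold: float = 0.1
) -> pd.DataFrame:
    """Binarized alternative to Pearson: Matthews correlation of "significantly
    up" indicators (sign of FC gated by q < threshold) between condition
    columns."""
    up = ((fc > 0) & (q < q_threshold)).astype(int)
    cols = list(fc.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            va, vb = up[a].to_numpy(), up[b].to_numpy()
            tp = int(((va == 1) & (vb == 1)).sum())
            tn = int(((va == 0) & (vb == 0)).sum())
            fp = int(((va == 0) & (vb == 1)).sum())
            fn = int(((va == 1) & (vb == 0)).sum())
            denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            mcc = (tp * tn - fp * fn) / denom if denom > 0 else np.nan
            out.loc[a, b] = out.loc[b, a] = mcc
    return out


def _highest_dose_profile(profiles, chemical: str):
    chem_profiles = [p for p in profiles if p.chemical == chemical]
    if not chem_profiles:
        raise ValueError(f"chemical absent from profiles: {chemical}")
    return max(chem_profiles, key=lambda p: p.dose_level)


def common_genes(
    profiles,
    chemicals: list[str],
    rule: str = "intersection",
    at_least_k: int | None = None,
    q_threshold: float = 0.1,
) -> CommonGeneSet:
    """Consensus of significantly changed genes at the highest dose.

    Per chemical, the significant set is genes with q < ``q_threshold`` in its
    highest-dose profile.  ``rule="intersection"`` keeps genes significant in
    every listed chemical; ``rule="at_least_k"`` keeps genes significant in at
    least ``at_least_k`` of them.
    """
    if rule not in {"intersection", "at_least_k"}:
        raise ValueError(f"unknown rule: {rule}")
    sets: dict[str, set[str]] = {}
    for chem in chemicals:
        prof = _highest_dose_profile(profiles, chem)
        sets[chem] = set(prof.table.index[prof.table["q"] < q_threshold])
    if rule == "intersection":
        members = set.intersection(*sets.values()) if sets else set()
        k = len(chemicals)
    else:
        if at_least_k is None or not (1 <= at_least_k <= len(chemicals)):
            raise ValueError("at_least_k must be in 1..len(chemicals)")
        counts: dict[str, int] = {}
        for s in sets.values():
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        members = {g for g, c in counts.items() if c >= at_least_k}
        k = at_least_k
    return CommonGeneSet(
        chemicals=list(chemicals),
        rule=f"{rule}(k={k})",
        q_threshold=q_threshold,
        members=sorted(members),
        per_chemical_sets=sets,
    )


def pairwise_significant_counts(
    profiles, chemicals: list[str], q_threshold: float = 0.1
) -> pd.DataFrame:
    """Chemical x chemical matrix of shared highest-dose significant genes
    (diagonal: per-chemical significant counts)."""
    sets = {
        chem: set(
            _highest_dose_profile(profiles, chem).table.pipe(
                lambda t: t.index[t["q"] < q_threshold]
            )
        )
        for chem in chemicals
    }
    out = pd.DataFrame(0, index=chemicals, columns=chemicals, dtype=int)
    for a in chemicals:
        for b in chemicals:
            out.loc[a, b] = len(sets[a] & sets[b])
    return out
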