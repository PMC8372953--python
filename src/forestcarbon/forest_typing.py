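"""Forest-type classification of inventory plots.

Plots are described by their per-plot species IVI profile (each row sums to
100 under the paper_100 convention) and grouped by agglomerative clustering
with Euclidean distance.  Two diagnostics common in vegetation analysis are
reported alongside the dendrogram:

* chaining percent — the share of merges that attach a single plot to an
  already-formed group of two or more; high values flag the chaining
  pathology of single-linkage-like trees;
* information remaining — the percent of the total sum of squares about the
  grand mean not yet absorbed into within-group scatter, per merge step.
  Cutting the tree "at p% information remaining" picks the coarsest
  partition that still retains at least p%.

Linkages: ward / average / complete (scipy), plus a flexible-beta
(Lance-Williams, beta = -0.25) agglomerator for compatibility with the
default of classic vegetation-analysis software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .inventory import PlotInventory, importance_values

LINKAGES = ("ward", "average", "complete", "flexible_beta")


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering of plots."""

    labels: list[str]  # leaf labels in input order
    linkage_matrix: np.ndarray  # scipy format: (n-1, 4)
    linkage: str
    chaining_percent: float
    information_remaining_curve: np.ndarray  # percent, index = merge step (0..n-1)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


@dataclass
class ForestTypeAssignment:
    """Plot -> forest-type label mapping."""

    assignment: dict[str, str]
    n_types: int

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for plot, t in self.assignment.items():
            out.setdefault(t, []).append(plot)
        return out


def build_ivi_matrix(plots: list[PlotInventory]) -> pd.DataFrame:
    """Plot x species matrix of per-plot IVI (paper_100: rows sum to 100).

    Each row is the IVI table of that single plot, using the subplot quadrat
    level when subplot ids are present; species absent from a plot get 0.
    """
    if not plots:
        raise ValueError("plots must be non-empty")
    rows = {}
    for p in plots:
        if not p.records:
            raise ValueError(f"plot {p.plot_id!r} has no tree records")
        tab = importance_values([p], quadrat="auto", convention="paper_100")
        rows[p.plot_id] = tab["ivi"]
    matrix = pd.DataFrame(rows).T.fillna(0.0)
    matrix = matrix.reindex(sorted(matrix.columns), axis=1)
    matrix.index.name = "plot"
    return matrix


def _flexible_beta_linkage(dist: np.ndarray, beta: float = -0.25) -> np.ndarray:
    """Lance-Williams agglomeration with the flexible-beta update.

    d(k, i+j) = alpha*d(k,i) + alpha*d(k,j) + beta*d(i,j), alpha = (1-beta)/2.
    Returns a scipy-format linkage matrix.  Ties in the minimum distance are
    broken toward the lowest cluster-id pair, so the result is deterministic.
    """
    d = squareform(dist) if dist.ndim == 1 else dist.copy().astype(float)
    n = d.shape[0]
    alpha = (1.0 - beta) / 2.0
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    next_id = n
    dmat = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[(i, j)] = d[i, j]

    def get(i: int, j: int) -> float:
        return dmat[(i, j) if i < j else (j, i)]

    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = get(i, j)
                key = (dij, min(i, j), max(i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = get(i, j)
        Z[step] = [min(i, j), max(i, j), dij, sizes[i] + sizes[j]]
        for k in active:
            if k in (i, j):
                continue
            dmat[(min(k, next_id), max(k, next_id))] = (
                alpha * get(k, i) + alpha * get(k, j) + beta * dij
            )
        sizes[next_id] = sizes[i] + sizes[j]
        active.remove(i)
        active.remove(j)
        active.append(next_id)
        next_id += 1
    return Z


def _chaining_percent(Z: np.ndarray, n: int) -> float:
    """Percent of merges that join a singleton to a group of size >= 2."""
    if len(Z) == 0:
        return 0.0
    sizes = {i: 1 for i in range(n)}
    chain = 0
    for step, (a, b, _h, size) in enumerate(Z):
        sa, sb = sizes[int(a)], sizes[int(b)]
        if (sa == 1) != (sb == 1) and max(sa, sb) >= 2:
            chain += 1
        sizes[n + step] = int(size)
    return 100.0 * chain / len(Z)


def _partitions_by_step(Z: np.ndarray, n: int) -> list[np.ndarray]:
    """Leaf -> cluster-id arrays after 0, 1, ..., n-1 merges."""
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    labels = np.arange(n)
    parts = [labels.copy()]
    for step, (a, b, _h, _s) in enumerate(Z):
        new = members[int(a)] + members[int(b)]
        members[n + step] = new
        labels[new] = n + step
        del members[int(a)], members[int(b)]
        parts.append(labels.copy())
    return parts


def _information_remaining_curve(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Percent of total SS about the grand mean outside within-group scatter.

    100% before any merge (every plot its own group, within-SS = 0), 0% at
    one group (within-SS = total SS).  Degenerate data (all rows identical,
    total SS = 0) reports 100% throughout except 0% at the final step.
    """
    n = X.shape[0]
    grand = X.mean(axis=0)
    total_ss = float(((X - grand) ** 2).sum())
    curve = np.zeros(n)
    for step, labels in enumerate(_partitions_by_step(Z, n)):
        w = 0.0
        for lab in np.unique(labels):
            rows = X[labels == lab]
            w += float(((rows - rows.mean(axis=0)) ** 2).sum())
        if total_ss > 0:
            curve[step] = 100.0 * (1.0 - w / total_ss)
        else:
            curve[step] = 0.0 if step == n - 1 else 100.0
    return curve


def cluster_plots(
    matrix: pd.DataFrame,
    linkage: str = "ward",
    k: int | None = None,
    cut_percent: float | None = None,
) -> tuple[Dendrogram, ForestTypeAssignment]:
    """Cluster plots on their IVI profiles (Euclidean distance).

    Exactly one of ``k`` (number of groups) or ``cut_percent`` (cut the tree
    at that information-remaining level: the coarsest partition retaining at
    least that percent) selects the partition; with neither given, k = 2.
    Type labels are T1, T2, ... ordered by first plot appearance.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two plots to cluster")
    if k is not None and cut_percent is not None:
        raise ValueError("give either k or cut_percent, not both")
    if k is not None and not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")

    if linkage == "flexible_beta":
        Z = _flexible_beta_linkage(pdist(X), beta=-0.25)
    else:
        Z = hierarchy.linkage(X, method=linkage, metric="euclidean")

    curve = _information_remaining_curve(X, Z)
    dend = Dendrogram(
        labels=list(matrix.index),
        linkage_matrix=Z,
        linkage=linkage,
        chaining_percent=_chaining_percent(Z, n),
        information_remaining_curve=curve,
    )

    if k is None and cut_percent is None:
        k = 2
    if cut_percent is not None:
        if not (0.0 <= cut_percent <= 100.0):
            raise ValueError("cut_percent must be in [0, 100]")
        # coarsest partition (most merges) with info remaining >= cut_percent
        steps = np.flatnonzero(curve >= cut_percent - 1e-9)
        step = int(steps.max()) if steps.size else 0
        labels = _partitions_by_step(Z, n)[step]
    else:
        labels = _partitions_by_step(Z, n)[n - k]

    type_of: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for plot, lab in zip(matrix.index, labels):
        if lab not in type_of:
            type_of[lab] = f"T{len(type_of) + 1}"
        assignment[str(plot)] = type_of[lab]
    return dend, ForestTypeAssignment(assignment=assignment, n_types=len(type_of))


def information_remaining(dendrogram: Dendrogram, step: int) -> float:
    """Information remaining (percent) after ``step`` merges (0-based)."""
    curve = dendrogram.information_remaining_curve
    if not (0 <= step < len(curve)):
        raise ValueError(f"step must be in [0, {len(curve) - 1}], got {step}")
    return float(curve[step])
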