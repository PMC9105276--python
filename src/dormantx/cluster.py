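"""Canberra-distance Ward minimum-variance clustering and leaf ordering.

Ward.D2 semantics: the Lance–Williams recurrence is applied to *squared*
dissimilarities,

    d2(k, i∪j) = [(n_i+n_k) d2(k,i) + (n_j+n_k) d2(k,j) − n_k d2(i,j)]
                 / (n_i + n_j + n_k),

and merge heights are reported on the original (unsquared) scale as
sqrt(d2). Ties are broken by the smallest (index_a, index_b) pair of
cluster creation indices (leaves 0..n−1, then n, n+1, ... in merge order),
which makes the dendrogram deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class MatrixValidationError(ValueError):
    pass


class DimensionError(ValueError):
    pass


def canberra_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Canberra distance: sum_i |x_i − y_i| / (|x_i| + |y_i|).

    Coordinates with x_i = y_i = 0 contribute 0 (the 0/0 convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError(
            f"length mismatch: {x.shape} vs {y.shape}")
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    terms = np.divide(num, den, out=np.zeros_like(num), where=den != 0)
    return float(terms.sum())


def pairwise_canberra(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Symmetric Canberra distance matrix over the rows of ``matrix``."""
    from scipy.spatial.distance import pdist, squareform
    arr = np.asarray(matrix, dtype=float)
    return squareform(pdist(arr, metric="canberra"))


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges[t] = (a, b, height, size)`` joins clusters with creation
    indices a < b into a new cluster with index ``n_leaves + t``.
    """

    merges: list[tuple[int, int, float, int]]
    leaves: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(
                f"{n} leaves require {n - 1} merges, got {len(self.merges)}")

    def to_scipy_linkage(self) -> np.ndarray:
        """The merge history as a scipy-style (n−1) x 4 linkage matrix."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges],
                        dtype=float)

    def to_merge_table(self, path: str | Path | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(self.merges,
                             columns=["cluster_a", "cluster_b",
                                      "height", "size"])
        frame.index.name = "merge"
        if path is not None:
            frame.to_csv(path, sep="\t", float_format="%.6g")
        return frame

    def to_newick(self, path: str | Path | None = None) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaves[i] for i in range(n)}
        for t, (a, b, h, _s) in enumerate(self.merges):
            for child in (a, b):
                blen = max(h - height[child], 0.0)
                node[child] = f"{node[child]}:{blen:.6g}"
            node[n + t] = f"({node[a]},{node[b]})"
            height[n + t] = h
        text = node[n + len(self.merges) - 1] + ";" if n > 1 else \
            f"{self.leaves[0]};"
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _validate_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise MatrixValidationError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise MatrixValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise MatrixValidationError("distance matrix must have zero diagonal")
    if (dist < 0).any():
        raise MatrixValidationError("distances must be non-negative")
    return dist


def ward_d2_linkage(dist: np.ndarray | pd.DataFrame,
                    leaves: Sequence[str] | None = None) -> Dendrogram:
    """Agglomerative Ward.D2 clustering of a dissimilarity matrix."""
    if isinstance(dist, pd.DataFrame):
        if leaves is None:
            leaves = [str(x) for x in dist.index]
        dist = dist.to_numpy()
    dist = _validate_distance_matrix(dist)
    n = dist.shape[0]
    if leaves is None:
        leaves = [str(i) for i in range(n)]
    leaves = list(leaves)
    if len(leaves) != n:
        raise DimensionError("one leaf label per matrix row is required")

    # one matrix slot per original leaf; a merge reuses the first cluster's
    # slot and retires the second's
    d2 = dist.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    slot_id = np.arange(n)            # slot -> current cluster creation id
    alive = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=np.int64)
    merges: list[tuple[int, int, float, int]] = []
    for t in range(n - 1):
        # vectorized minimum, then exact (id_a, id_b) tie-break among the
        # pairs within floating tolerance of it
        vmin = d2.min()
        cand = np.argwhere(d2 <= vmin + 1e-15)
        best = None
        for i, j in cand:
            if i >= j:
                continue
            pair = tuple(sorted((int(slot_id[i]), int(slot_id[j]))))
            if best is None or pair < best[0]:
                best = (pair, int(i), int(j))
        (a, b), slot_a, slot_b = best
        if slot_id[slot_a] != a:      # keep slot of the earlier-created id
            slot_a, slot_b = slot_b, slot_a
        height = math.sqrt(max(d2[slot_a, slot_b], 0.0))
        na, nb = sizes[slot_a], sizes[slot_b]
        other = alive.copy()
        other[[slot_a, slot_b]] = False
        nk = sizes[other]
        updated = (((na + nk) * d2[other, slot_a]
                    + (nb + nk) * d2[other, slot_b]
                    - nk * d2[slot_a, slot_b]) / (na + nb + nk))
        d2[other, slot_a] = updated
        d2[slot_a, other] = updated
        d2[slot_b, :] = np.inf
        d2[:, slot_b] = np.inf
        alive[slot_b] = False
        sizes[slot_a] = na + nb
        slot_id[slot_a] = n + t
        merges.append((a, b, height, int(na + nb)))
    return Dendrogram(merges=merges, leaves=leaves)


def leaf_order(dendrogram: Dendrogram) -> list[str]:
    """Left-to-right depth-first leaf order.

    At each merge the earlier-created cluster (smaller creation index)
    is placed left.
    """
    n = len(dendrogram.leaves)
    if n == 1:
        return list(dendrogram.leaves)
    children: dict[int, tuple[int, int]] = {}
    for t, (a, b, _h, _s) in enumerate(dendrogram.merges):
        children[n + t] = (min(a, b), max(a, b))
    order: list[str] = []
    stack = [n + len(dendrogram.merges) - 1]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(dendrogram.leaves[node])
        else:
            left, right = children[node]
            stack.append(right)
            stack.append(left)
    return order


def cluster_matrix(values: pd.DataFrame, axis: str = "columns",
                   ) -> tuple[Dendrogram, list[str]]:
    """Cluster rows or columns of a matrix with Canberra + Ward.D2."""
    if axis == "columns":
        data = values.T
    elif axis == "rows":
        data = values
    else:
        raise DimensionError("axis must be 'rows' or 'columns'")
    labels = [str(x) for x in data.index]
    dist = pairwise_canberra(data.to_numpy())
    dend = ward_d2_linkage(dist, leaves=labels)
    return dend, leaf_order(dend)


def plot_heatmap(values: pd.DataFrame, path: str | Path,
                 z_scale_rows: bool = False) -> None:
    """Clustered heatmap (smoke-tested convenience; no layout guarantees)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = values.copy()
    if z_scale_rows:
        data = data.sub(data.mean(axis=1), axis=0)
        sd = data.std(axis=1).replace(0.0, 1.0)
        data = data.div(sd, axis=0)
    _rd, row_order = cluster_matrix(data, axis="rows")
    _cd, col_order = cluster_matrix(data, axis="columns")
    data = data.loc[row_order, col_order]
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * data.shape[1]),
                                    max(4, 0.12 * data.shape[0])))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
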