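"""Hierarchical clustering of copy-number profiles.

The default agglomeration is "ward.D": Ward's minimum-variance update
applied through the Lance-Williams recurrence directly to *unsquared*
Euclidean distances,

    d(i∪j, k) = ((n_i+n_k) d(i,k) + (n_j+n_k) d(j,k) - n_k d(i,j)) / (n_i+n_j+n_k)

with merge heights equal to the distance at which two clusters fuse.
(The common alternative, ward.D2, applies the same recurrence to squared
distances and reports the square root; both are available.)  Ties between
equally close pairs are broken deterministically towards the pair with the
lexicographically smallest (min cluster id, max cluster id).

Cluster ids follow the usual linkage convention: leaves are 0..n-1 and the
cluster created at step t is n+t, so results convert directly to a
scipy-style linkage matrix for plotting.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import SampleTable
from .matrix import CNVMatrix

_TIE_REL = 1e-12


@dataclass(frozen=True)
class Dendrogram:
    """Merge tree over n leaves: n-1 merges of (cluster a, cluster b, height)."""

    n_leaves: int
    merges: tuple[tuple[int, int, float], ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves needs n-1 merges")

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible (n-1, 4) linkage matrix."""
        sizes = {i: 1 for i in range(self.n_leaves)}
        Z = np.zeros((len(self.merges), 4))
        for t, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[self.n_leaves + t] = size
            Z[t] = (a, b, h, size)
        return Z

    def leaves(self, node: int) -> list[int]:
        out: list[int] = []
        stack = [node]
        while stack:  # iterative: trees can be deeper than the recursion limit
            cur = stack.pop()
            if cur < self.n_leaves:
                out.append(cur)
            else:
                a, b, _ = self.merges[cur - self.n_leaves]
                stack.extend((b, a))
        return out

    @property
    def leaf_order(self) -> list[int]:
        return self.leaves(self.n_leaves + len(self.merges) - 1)

    def to_newick(self) -> str:
        """Newick serialization; branch lengths are height differences so
        leaf depths reproduce the merge heights."""
        height_of = {i: 0.0 for i in range(self.n_leaves)}
        for t, (_, _, h) in enumerate(self.merges):
            height_of[self.n_leaves + t] = h

        def render(node: int, parent_h: float) -> str:
            bl = max(parent_h - height_of[node], 0.0)
            if node < self.n_leaves:
                return f"{self.labels[node]}:{bl:.6g}"
            a, b, h = self.merges[node - self.n_leaves]
            return f"({render(a, h)},{render(b, h)}):{bl:.6g}"

        root = self.n_leaves + len(self.merges) - 1
        a, b, h = self.merges[-1]
        return f"({render(a, h)},{render(b, h)});"


def _lw_update(method, di, dj, dij, ni, nj, nk):
    if method == "ward.D":
        return ((ni + nk) * di + (nj + nk) * dj - nk * dij) / (ni + nj + nk)
    if method == "ward.D2":
        return np.sqrt(
            ((ni + nk) * di**2 + (nj + nk) * dj**2 - nk * dij**2) / (ni + nj + nk)
        )
    if method == "average":
        return (ni * di + nj * dj) / (ni + nj)
    if method == "complete":
        return np.maximum(di, dj)
    if method == "single":
        return np.minimum(di, dj)
    raise ValueError(f"unknown agglomeration method {method!r}")


def linkage_from_distances(
    dist: np.ndarray,
    method: str = "ward.D",
    labels: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomerate a full symmetric distance matrix."""
    D = np.asarray(dist, dtype=float).copy()
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    ids = list(range(n))  # slot -> current cluster id
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    np.fill_diagonal(D, np.inf)
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        dmin = D.min()
        tol = _TIE_REL * (1.0 + abs(dmin))
        # lexicographically smallest (min id, max id) among tied closest
        # pairs: the slot with the smallest id that attains the minimum,
        # then its smallest-id partner
        mask = D <= dmin + tol
        ids_arr = np.asarray(ids)
        rows = np.where(mask.any(axis=1))[0]
        i = int(rows[np.argmin(ids_arr[rows])])
        partners = np.where(mask[i])[0]
        j = int(partners[np.argmin(ids_arr[partners])])
        ida, idb = min(ids[i], ids[j]), max(ids[i], ids[j])
        h = float(D[i, j])
        merges.append((ida, idb, h))
        # slot i hosts the merged cluster; retire slot j
        alive[i] = alive[j] = False
        k = np.where(alive)[0]
        alive[i] = True
        if k.size:
            D[i, k] = D[k, i] = _lw_update(
                method, D[i, k], D[j, k], D[i, j], sizes[i], sizes[j], sizes[k]
            )
        sizes[i] = sizes[i] + sizes[j]
        D[j, :] = D[:, j] = np.inf
        ids[i] = n + step
    lab = tuple(labels) if labels is not None else tuple(str(i) for i in range(n))
    return Dendrogram(n_leaves=n, merges=tuple(merges), labels=lab)


def ward_linkage(
    data,
    on: str = "rows",
    metric: str = "euclidean",
    method: str = "ward.D",
    labels: Sequence[str] | None = None,
) -> Dendrogram:
    """Cluster the rows (samples) or columns (windows) of a matrix.

    ``data`` is a :class:`CNVMatrix` or any 2-D array.
    """
    if isinstance(data, CNVMatrix):
        X = data.values.astype(float)
        if labels is None:
            labels = data.samples if on == "rows" else data.windows.labels
    else:
        X = np.asarray(data, dtype=float)
    if on == "columns":
        X = X.T
    elif on != "rows":
        raise ValueError("on must be 'rows' or 'columns'")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    D = squareform(pdist(X, metric=metric))
    return linkage_from_distances(D, method=method, labels=labels)


@dataclass(frozen=True)
class HeatmapLayout:
    """A clustered matrix ready for rendering."""

    values: np.ndarray  # reordered values
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    row_dendrogram: Dendrogram
    col_dendrogram: Dendrogram | None
    row_order: tuple[int, ...]
    col_order: tuple[int, ...]
    feature: str | None = None
    feature_values: tuple | None = None


def build_heatmap(
    m: CNVMatrix,
    sample_table: SampleTable | None = None,
    feature: str | None = None,
    cluster_windows: bool = False,
    metric: str = "euclidean",
    method: str = "ward.D",
):
    """Build heatmap layout(s): samples always clustered, windows clustered
    only on request (otherwise kept in genomic order).

    With a sample table and no explicit feature, one layout per annotated
    feature is returned (a list); otherwise a single layout.
    """
    if feature is not None:
        if sample_table is None:
            raise ValueError("a feature requires a sample table")
        if feature not in sample_table.features:
            raise KeyError(f"unknown feature {feature!r}")
    row_d = ward_linkage(m, on="rows", metric=metric, method=method)
    row_order = tuple(row_d.leaf_order)
    if cluster_windows:
        col_d = ward_linkage(m, on="columns", metric=metric, method=method)
        col_order = tuple(col_d.leaf_order)
    else:
        col_d = None
        col_order = tuple(range(len(m.windows)))

    def layout(feat: str | None) -> HeatmapLayout:
        fvals = (
            tuple(
                sample_table.values_for(feat, [m.samples[i] for i in row_order])
            )
            if feat is not None
            else None
        )
        return HeatmapLayout(
            values=m.values[np.ix_(row_order, col_order)],
            row_labels=tuple(m.samples[i] for i in row_order),
            col_labels=tuple(m.windows.labels[i] for i in col_order),
            row_dendrogram=row_d,
            col_dendrogram=col_d,
            row_order=row_order,
            col_order=col_order,
            feature=feat,
            feature_values=fvals,
        )

    if feature is None and sample_table is not None and sample_table.features:
        return [layout(f) for f in sample_table.features]
    return layout(feature)
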