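"""Agglomerative clustering of binding-frequency matrices.

Rows (subfamilies) or columns (TFs/motifs) of a frequency matrix are
clustered with Manhattan distances and either complete linkage or the
"ward.D2" convention (Ward's criterion on squared input distances, with
merge heights reported on the unsquared scale).  The implementation is a
plain Lance-Williams agglomeration with a deterministic tie-break —
among minimal-distance pairs the lexicographically smallest pair of
cluster indices merges first — so results are reproducible across runs
and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "Dendrogram",
    "manhattan_distances",
    "agglomerate",
    "cut_clusters",
]

_LINKAGES = ("complete", "ward_on_distances")


@dataclass(frozen=True)
class Dendrogram:
    """Merge tree over labelled leaves.

    ``merges`` lists (cluster_a, cluster_b, height) with cluster ids
    0..n-1 for leaves and n, n+1, ... for successive merges (a < b).
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    @property
    def leaf_order(self) -> list[str]:
        """Left-before-right leaf ordering of the merge tree."""
        n = self.n_leaves
        children = {n + k: (a, b) for k, (a, b, _) in enumerate(self.merges)}
        order: list[str] = []

        def walk(node: int) -> None:
            if node < n:
                order.append(self.labels[node])
            else:
                a, b = children[node]
                walk(a)
                walk(b)

        walk(n + len(self.merges) - 1) if self.merges else order.extend(self.labels)
        return order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["cluster_a", "cluster_b", "height"])


def manhattan_distances(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Manhattan (city-block) distances between matrix rows."""
    X = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; drop undefined rows first")
    return cdist(X, X, metric="cityblock")


def agglomerate(
    distances: np.ndarray,
    linkage: str = "complete",
    labels: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomerative clustering from a pairwise distance matrix.

    ``linkage`` is "complete" or "ward_on_distances" (the ward.D2
    convention: squared distances internally, heights reported on the
    unsquared scale).  Ties are broken by the smallest (i, j) cluster
    index pair.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    n = D.shape[0]
    names = tuple(labels) if labels is not None else tuple(str(i) for i in range(n))
    if len(names) != n:
        raise ValueError("labels length must match matrix size")

    ward = linkage == "ward_on_distances"
    # working pairwise table among active clusters (squared scale for ward)
    work: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = D[i, j]
            work[(i, j)] = d * d if ward else d
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        (i, j), dmin = min(work.items(), key=lambda kv: (kv[1], kv[0]))
        height = float(np.sqrt(dmin)) if ward else float(dmin)
        merges.append((i, j, height))
        ni, nj = sizes[i], sizes[j]
        active.discard(i)
        active.discard(j)
        new_d: dict[tuple[int, int], float] = {}
        for k in active:
            dki = work.pop((min(i, k), max(i, k)))
            dkj = work.pop((min(j, k), max(j, k)))
            if ward:
                nk = sizes[k]
                d = ((ni + nk) * dki + (nj + nk) * dkj - nk * dmin) / (ni + nj + nk)
            else:
                d = max(dki, dkj)
            new_d[(k, next_id)] = d
        work.pop((i, j))
        work.update(new_d)
        sizes[next_id] = ni + nj
        active.add(next_id)
        next_id += 1
    return Dendrogram(labels=names, merges=tuple(merges))


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut the merge tree into ``k`` clusters; returns label -> cluster id
    (ids 0..k-1, numbered by smallest member leaf index)."""
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError("k must be between 1 and the number of leaves")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    node_root = {i: i for i in range(n)}
    for step, (a, b, _h) in enumerate(dendrogram.merges[: n - k]):
        ra, rb = find(node_root[a]), find(node_root[b])
        parent[rb] = ra
        members[ra].extend(members.pop(rb))
        node_root[n + step] = ra
    groups = sorted(members.values(), key=min)
    out: dict[str, int] = {}
    for cid, leaves in enumerate(groups):
        for leaf in leaves:
            out[dendrogram.labels[leaf]] = cid
    return out
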