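"""Hierarchical clustering with the one-minus-correlation metric and
average linkage (UPGMA), plus deterministic heatmap ordering.

The agglomeration is implemented directly (O(n^3), trivial at the tens of
differential miRNAs this pipeline clusters) so that tie-breaking at equal
merge heights is fully specified: the candidate pair whose lexicographically
smallest member leaf comes first wins, which makes leaf order — and hence
the exported heatmap row order — reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = ["Dendrogram", "correlation_distance", "average_linkage", "to_newick"]


@dataclass
class Dendrogram:
    """Merge history and leaf order of an agglomerative clustering.

    ``merges`` lists (left_id, right_id, height, new_id) in merge order;
    ids 0..n-1 are leaves, n.. are internal nodes. ``labels`` names the
    leaves; ``leaf_order`` is the display permutation.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]
    leaf_order: list[str]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merges]


def correlation_distance(m: ExpressionMatrix | pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Pairwise d(i,j) = 1 - Pearson r over rows (miRNAs) or columns (samples)."""
    vals = m.values if isinstance(m, ExpressionMatrix) else m
    data = vals if axis == "rows" else vals.T
    if data.shape[0] < 2:
        raise ValueError("need at least 2 vectors to compute distances")
    arr = data.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    bad = np.asarray(data.index)[sd == 0]
    if len(bad):
        raise ValueError(f"constant vector(s), correlation undefined: {list(bad)}")
    r = np.corrcoef(arr)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # symmetrize away float noise
    return pd.DataFrame(d, index=data.index, columns=data.index)


def average_linkage(d: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance matrix.

    Inter-cluster distance is the unweighted mean over all cross pairs of
    original points. Ties at equal candidate heights break toward the pair
    containing the lexicographically smallest leaf label.
    """
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    labels = [str(x) for x in d.index]
    n = len(labels)

    # active cluster id -> (member leaf indices, min member label)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    minlab: dict[int, str] = {i: labels[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(arr[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    active = set(range(n))

    def key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                h = dist[key(i, j)]
                lab = min(minlab[i], minlab[j]), max(minlab[i], minlab[j])
                cand = (h, lab[0], lab[1], i, j)
                if best is None or cand < best:
                    best = cand
        h, _, _, i, j = best
        new = next_id
        next_id += 1
        # order children so the subtree holding the smaller label comes first
        left, right = (i, j) if minlab[i] <= minlab[j] else (j, i)
        children[new] = (left, right)
        merges.append((left, right, h, new))
        mem = members[i] + members[j]
        for k in active:
            if k in (i, j):
                continue
            # unweighted average over original point pairs
            dik = dist[key(i, k)] * len(members[i])
            djk = dist[key(j, k)] * len(members[j])
            dist[key(new, k)] = (dik + djk) / len(mem)
        members[new] = mem
        minlab[new] = min(minlab[i], minlab[j])
        active.discard(i)
        active.discard(j)
        active.add(new)

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    root = next(iter(active)) if active else 0
    order = [labels[i] for i in leaves(root)] if n > 1 else list(labels)
    return Dendrogram(merges=merges, labels=labels, leaf_order=order)



def to_newick(dend: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string with branch heights."""
    n = len(dend.labels)
    children = {new: (a, b, h) for a, b, h, new in dend.merges}
    height = {i: 0.0 for i in range(n)}
    for a, b, h, new in dend.merges:
        height[new] = h

    def render(node: int) -> str:
        if node < n:
            return dend.labels[node]
        a, b, h = children[node]
        bl_a = (h - height[a]) / 2.0
        bl_b = (h - height[b]) / 2.0
        return f"({render(a)}:{bl_a:.6g},{render(b)}:{bl_b:.6g})"

    if not dend.merges:
        return (dend.labels[0] if dend.labels else "") + ";"
    root = dend.merges[-1][3]
    return render(root) + ";"
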