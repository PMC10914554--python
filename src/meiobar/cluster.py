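"""Group-average (UPGMA) agglomerative clustering with a deterministic tie rule.

This is the species-proxy primitive of the pipeline: amplicon sequence
variants are merged bottom-up under pair-count-weighted average linkage and
the dendrogram is cut *strictly below* a dissimilarity threshold, so a merge
at exactly the threshold does not join clusters. The same engine clusters
community profiles on Bray-Curtis dissimilarity.

Tie-breaking when two candidate merges share the minimal height: the pair
whose lexicographically smallest member id is smallest wins (then the other
member id). This makes the partition invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Merge:
    height: float
    left: tuple[str, ...]   # member ids of the two clusters being joined
    right: tuple[str, ...]


def upgma(d: np.ndarray, ids: list[str]) -> list[Merge]:
    """Full agglomeration of a square symmetric dissimilarity matrix.

    Average linkage: d(C, A+B) = (|A| d(C,A) + |B| d(C,B)) / (|A|+|B|),
    i.e. the arithmetic mean over all cross pairs. Returns the n-1 merges
    in the order performed. O(n^3), fine for the library sizes involved.
    """
    d = np.asarray(d, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if n != len(set(ids)):
        raise ValueError("duplicate ids")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")

    # active clusters: list of (sorted member tuple, representative = min id)
    members: list[tuple[str, ...]] = [(i,) for i in ids]
    sizes = np.ones(n)
    dist = d.copy().astype(float)
    np.fill_diagonal(dist, np.inf)
    active = list(range(n))
    merges: list[Merge] = []

    while len(active) > 1:
        best = None
        best_key = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                h = dist[i, j]
                ra, rb = members[i][0], members[j][0]
                key = (h, min(ra, rb), max(ra, rb))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        h = dist[i, j]
        merges.append(Merge(h, members[i], members[j]))
        # merged cluster replaces slot i; j is retired
        new_members = tuple(sorted(members[i] + members[j]))
        for k in active:
            if k in (i, j):
                continue
            dist[i, k] = dist[k, i] = (
                sizes[i] * dist[i, k] + sizes[j] * dist[j, k]
            ) / (sizes[i] + sizes[j])
        members[i] = new_members
        sizes[i] += sizes[j]
        active.remove(j)

    return merges


def cut(merges: list[Merge], ids: list[str], threshold: float) -> list[set[str]]:
    """Partition induced by applying only merges with height < threshold."""
    if not (0 < threshold <= 1e9):
        raise ValueError("cut threshold must be positive")
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in merges:
        if m.height < threshold:
            a, b = find(m.left[0]), find(m.right[0])
            parent[max(a, b)] = min(a, b)
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    # deterministic order: by smallest member id
    return [groups[k] for k in sorted(groups)]


def cluster(d: np.ndarray, ids: list[str], threshold: float) -> list[set[str]]:
    """UPGMA + strict cut in one call."""
    if len(ids) == 1:
        return [set(ids)]
    return cut(upgma(d, ids), ids, threshold)


def to_newick(merges: list[Merge], ids: list[str]) -> str:
    """Dendrogram as a Newick string; branch lengths from merge heights.

    Leaf branch length = height of the merge that absorbs the leaf (heights
    are cophenetic dissimilarities, halved as in an ultrametric tree).
    """
    node: dict[tuple[str, ...], str] = {(i,): i for i in ids}
    height: dict[tuple[str, ...], float] = {(i,): 0.0 for i in ids}
    for m in merges:
        key = tuple(sorted(m.left + m.right))
        h = m.height / 2.0
        bl_l = max(h - height[m.left], 0.0)
        bl_r = max(h - height[m.right], 0.0)
        node[key] = f"({node[m.left]}:{bl_l:.6g},{node[m.right]}:{bl_r:.6g})"
        height[key] = h
        del node[m.left], node[m.right], height[m.left], height[m.right]
    if len(node) != 1:
        # disconnected (shouldn't happen: upgma always fully agglomerates)
        return "(" + ",".join(node.values()) + ");"
    return next(iter(node.values())) + ";"
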