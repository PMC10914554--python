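"""Resemblance-based community statistics.

Square-root transformed abundance profiles are compared by Bray-Curtis
similarity (0-100 scale), clustered into a group-average dendrogram, and
tested pairwise by one-way permutational multivariate ANOVA (pseudo-F on the
dissimilarity matrix, unrestricted permutation of raw labels). BIOENV
exhaustively searches abiotic-variable subsets for the Euclidean distance
structure that best rank-correlates (Spearman, average ranks on ties) with
the biotic dissimilarities; significance is declared against the maximal rho
achievable under random relabelings of the abiotic table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from . import cluster as _cluster

log = logging.getLogger(__name__)


@dataclass
class BioenvResult:
    best_subset: tuple[str, ...]
    rho: float
    per_size: dict[int, tuple[tuple[str, ...], float]]
    permutation_threshold: float
    n_permutations: int

    @property
    def significant(self) -> bool:
        return self.rho > self.permutation_threshold


def bray_curtis(matrix: pd.DataFrame, transform: str = "sqrt") -> pd.DataFrame:
    """Bray-Curtis similarity (percent) between sample rows.

    `matrix` is samples x ASV-3 abundances. Default square-root transform
    damps dominant taxa. Pairs where both samples are all-zero have no
    defined similarity; such samples are dropped with a warning.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    m = matrix.astype(float)
    empty = m.index[(m.sum(axis=1) == 0)].tolist()
    if empty:
        log.warning("dropping all-zero profiles (undefined similarity): %s", empty)
        m = m.drop(index=empty)
    if transform == "sqrt":
        m = np.sqrt(m)
    elif transform not in (None, "none"):
        raise ValueError(f"unknown transform {transform!r}")
    v = m.to_numpy()
    num = np.abs(v[:, None, :] - v[None, :, :]).sum(axis=2)
    den = (v[:, None, :] + v[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 100.0 * (1.0 - num / den)
    np.fill_diagonal(sim, 100.0)
    return pd.DataFrame(sim, index=m.index, columns=m.index)


def dendrogram(similarity: pd.DataFrame):
    """Group-average tree on dissimilarity = 100 - similarity.

    Returns (merges, ids); use `cut_similarity` for flat clusters and
    `to_newick` for export.
    """
    ids = [str(i) for i in similarity.index]
    d = 100.0 - similarity.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    return _cluster.upgma(d, ids), ids


def cut_similarity(merges, ids, similarity_level: float) -> list[set[str]]:
    """Flat clusters at a similarity level (e.g. 20 or 40 on the 0-100 scale)."""
    return _cluster.cut(merges, ids, 100.0 - similarity_level)


def to_newick(merges, ids) -> str:
    return _cluster.to_newick(merges, ids)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from squared dissimilarities."""
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    if ss_w <= 0:
        return np.inf
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def pairwise_permutation_test(
    dissimilarity: pd.DataFrame,
    groups: dict[str, list[str]] | pd.Series,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise one-way PERMANOVA on a dissimilarity matrix.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm). Groups of size 1 are
    skipped with a warning. Returns a tidy frame with F, p and group sizes.
    """
    if isinstance(groups, pd.Series):
        groups = {g: list(groups.index[groups == g]) for g in groups.unique()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    rows = []
    for ga, gb in combinations(sorted(groups), 2):
        ids_a, ids_b = groups[ga], groups[gb]
        if len(ids_a) < 2 or len(ids_b) < 2:
            log.warning("skipping pair (%s, %s): group of size < 2", ga, gb)
            continue
        ids = list(ids_a) + list(ids_b)
        d2 = dissimilarity.loc[ids, ids].to_numpy(dtype=float) ** 2
        labels = np.array([0] * len(ids_a) + [1] * len(ids_b))
        f_obs = _pseudo_f(d2, labels)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if _pseudo_f(d2, perm) >= f_obs:
                count += 1
        p = (1 + count) / (1 + n_perm)
        rows.append({"group_a": ga, "group_b": gb, "n_a": len(ids_a),
                     "n_b": len(ids_b), "pseudo_F": f_obs, "p": p,
                     "significant": p < 0.05})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BIOENV


def _condensed(square: pd.DataFrame, ids) -> np.ndarray:
    return squareform(square.loc[ids, ids].to_numpy(dtype=float), checks=False)


def _best_subsets(biotic_cond: np.ndarray, z: np.ndarray, names: list[str]):
    """Exhaustive search: best Spearman rho per subset size and overall."""
    per_size: dict[int, tuple[tuple[str, ...], float]] = {}
    best = ((), -np.inf)
    k = len(names)
    for size in range(1, k + 1):
        size_best = ((), -np.inf)
        for subset in combinations(range(k), size):
            dist = pdist(z[:, subset])
            rho = spearmanr(biotic_cond, dist).statistic
            if np.isnan(rho):
                rho = 0.0
            if rho > size_best[1]:
                size_best = (tuple(names[i] for i in subset), rho)
        per_size[size] = size_best
        if size_best[1] > best[1]:
            best = size_best
    return best, per_size


def bioenv(
    biotic_dissimilarity: pd.DataFrame,
    abiotic: pd.DataFrame,
    n_perm: int = 99,
    seed: int = 0,
) -> BioenvResult:
    """Best abiotic-variable subset matching the biotic structure.

    `abiotic` holds one row per sample (index matching the biotic matrix)
    and one numeric column per variable; columns are z-scored internally,
    zero-variance columns are excluded with a warning. The permutation
    threshold is the maximum best-subset rho over `n_perm` random row
    relabelings of the abiotic table.
    """
    ids = [i for i in biotic_dissimilarity.index if i in abiotic.index]
    if len(ids) < 3:
        raise ValueError("need at least three matched samples")
    ab = abiotic.loc[ids].astype(float)
    keep = []
    for c in ab.columns:
        if ab[c].std(ddof=1) == 0 or ab[c].isna().any():
            log.warning("excluding abiotic variable %r (constant or missing)", c)
        else:
            keep.append(c)
    if not keep:
        raise ValueError("no usable abiotic variables")
    z = ((ab[keep] - ab[keep].mean()) / ab[keep].std(ddof=1)).to_numpy()
    biotic_cond = _condensed(biotic_dissimilarity, ids)

    (best_subset, rho), per_size = _best_subsets(biotic_cond, z, keep)

    rng = np.random.default_rng(seed)
    thresh = -np.inf
    for _ in range(n_perm):
        perm = rng.permutation(len(ids))
        (_, r), _ = _best_subsets(biotic_cond, z[perm], keep)
        thresh = max(thresh, r)
    return BioenvResult(
        best_subset=best_subset,
        rho=float(rho),
        per_size=per_size,
        permutation_threshold=float(thresh),
        n_permutations=n_perm,
    )


def shared_asv_matrix(
    site_sets: dict[str, set[str]], convention: str = "union"
) -> pd.DataFrame:
    """Percent shared ASV-3s between sites.

    convention="union": |A & B| / |A | B| * 100 (Jaccard, symmetric);
    convention="smaller": |A & B| / min(|A|, |B|) * 100.
    """
    if convention not in ("union", "smaller"):
        raise ValueError("convention must be 'union' or 'smaller'")
    sites = sorted(site_sets)
    out = pd.DataFrame(np.nan, index=sites, columns=sites, dtype=float)
    for s in sites:
        if not site_sets[s]:
            log.warning("site %s has an empty ASV-3 set", s)
    for i, a in enumerate(sites):
        for b in sites[i:]:
            A, B = site_sets[a], site_sets[b]
            if not A or not B:
                continue
            inter = len(A & B)
            denom = len(A | B) if convention == "union" else min(len(A), len(B))
            out.loc[a, b] = out.loc[b, a] = 100.0 * inter / denom
    return out
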