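"""Bray-Curtis structure, permutation tests, BIOENV and shared-ASV matrices."""

import itertools

import numpy as np
import pandas as pd
import pytest

from meiobar.community import (bioenv, bray_curtis, cut_similarity, dendrogram,
                               pairwise_permutation_test, shared_asv_matrix,
                               to_newick)


def naive_rank(v):
    """Average ranks with ties, computed from first principles."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def naive_bioenv(biotic_cond, z, names):
    """Independent enumerator with hand-rolled Spearman correlation."""
    rb = naive_rank(biotic_cond)
    best = (None, -np.inf)
    per_size = {}
    for size in range(1, len(names) + 1):
        sbest = (None, -np.inf)
        for subset in itertools.combinations(range(len(names)), size):
            pts = z[:, subset]
            n = len(pts)
            dist = [np.sqrt(((pts[i] - pts[j]) ** 2).sum())
                    for i in range(n) for j in range(i + 1, n)]
            ra = naive_rank(dist)
            rho = np.corrcoef(rb, ra)[0, 1]
            if rho > sbest[1]:
                sbest = (tuple(names[k] for k in subset), rho)
        per_size[size] = sbest
        if sbest[1] > best[1]:
            best = sbest
    return best, per_size


class TestBrayCurtis:
    def test_identical_profiles_score_100(self):
        m = pd.DataFrame([[3, 1, 0], [3, 1, 0]], index=["a", "b"])
        sim = bray_curtis(m)
        assert sim.loc["a", "b"] == pytest.approx(100.0)

    def test_disjoint_profiles_score_0(self):
        m = pd.DataFrame([[5, 0], [0, 7]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(0.0)

    def test_untransformed_formula_evaluation(self):
        m = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["a", "b"])
        sim = bray_curtis(m, transform="none")
        assert sim.loc["a", "b"] == pytest.approx(50.0)

    def test_all_zero_profile_dropped(self):
        m = pd.DataFrame([[1, 2], [0, 0], [2, 1]], index=["a", "z", "b"])
        sim = bray_curtis(m)
        assert list(sim.index) == ["a", "b"]

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 20, (6, 10)).astype(float) + 0.1)
        sim = bray_curtis(m)
        v = sim.to_numpy()
        assert np.allclose(v, v.T)
        assert (v >= -1e-9).all() and (v <= 100 + 1e-9).all()


class TestDendrogram:
    def test_identical_profiles_merge_at_zero(self):
        m = pd.DataFrame([[2, 2], [2, 2]], index=["a", "b"])
        merges, ids = dendrogram(bray_curtis(m))
        assert merges[0].height == pytest.approx(0.0)

    def test_planted_two_block_structure(self):
        rng = np.random.default_rng(1)
        block1 = rng.integers(20, 30, (3, 8)).astype(float)
        block2 = np.zeros((3, 8))
        block2[:, :2] = rng.integers(20, 30, (3, 2))
        m = pd.DataFrame(np.vstack([block1, block2]),
                         index=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)])
        sim = bray_curtis(m)
        merges, ids = dendrogram(sim)
        parts = cut_similarity(merges, ids, 50.0)
        assert sorted(map(sorted, parts)) == [
            ["a0", "a1", "a2"], ["b0", "b1", "b2"]]

    def test_newick_roundtrips_through_dendropy(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.integers(1, 30, (5, 6)).astype(float),
                         index=[f"s{i}" for i in range(5)])
        merges, ids = dendrogram(bray_curtis(m))
        nwk = to_newick(merges, ids)
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == set(ids)


class TestPairwisePermutation:
    def _groups(self, n_per=4):
        return {"g1": [f"a{i}" for i in range(n_per)],
                "g2": [f"b{i}" for i in range(n_per)]}

    def _dissim(self, separation, n_per=4, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(2 * n_per, 3))
        pts[n_per:] += separation
        from scipy.spatial.distance import pdist, squareform
        ids = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
        return pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)

    def test_strong_separation_gives_minimal_p(self):
        # groups large enough that a random permutation essentially never
        # reproduces the observed partition (which would tie F_obs)
        res = pairwise_permutation_test(self._dissim(50.0, n_per=10),
                                        self._groups(n_per=10),
                                        n_perm=199, seed=1)
        assert res["p"].iloc[0] == pytest.approx(1 / 200)

    def test_seeded_determinism(self):
        d = self._dissim(1.0)
        a = pairwise_permutation_test(d, self._groups(), n_perm=99, seed=7)
        b = pairwise_permutation_test(d, self._groups(), n_perm=99, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_singleton_group_skipped(self):
        d = self._dissim(1.0)
        groups = {"g1": ["a0"], "g2": ["b0", "b1", "b2"]}
        res = pairwise_permutation_test(d, groups, n_perm=49, seed=0)
        assert res.empty

    def test_matches_exhaustive_permutation_oracle(self):
        # n=6 (3+3): only 20 label assignments; compare against full enumeration
        d = self._dissim(1.5, n_per=3, seed=3)
        groups = self._groups(n_per=3)
        from meiobar.community import _pseudo_f
        ids = groups["g1"] + groups["g2"]
        d2 = d.loc[ids, ids].to_numpy() ** 2
        labels = np.array([0, 0, 0, 1, 1, 1])
        f_obs = _pseudo_f(d2, labels)
        exact = [
            _pseudo_f(d2, np.array(perm))
            for perm in set(itertools.permutations(labels))
        ]
        p_exact = sum(f >= f_obs for f in exact) / len(exact)
        res = pairwise_permutation_test(d, groups, n_perm=4999, seed=5)
        # permutation p within binomial Monte-Carlo error of the exact value
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 5000)
        assert abs(res["p"].iloc[0] - p_exact) < 4 * mc_se + 1e-3


class TestBioenv:
    def _study(self, seed, n=10, k=4):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        z = rng.normal(size=(n, k))
        names = [f"v{j}" for j in range(k)]
        # biotic structure driven by the first two variables
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(z[:, :2]) + rng.normal(0, 0.1, n * (n - 1) // 2))
        d = np.abs(d)
        np.fill_diagonal(d, 0)
        biotic = pd.DataFrame(d, index=ids, columns=ids)
        abiotic = pd.DataFrame(z, index=ids, columns=names)
        return biotic, abiotic

    def test_perfect_rank_agreement_gives_rho_one(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(8)]
        z = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform
        biotic = pd.DataFrame(squareform(pdist(z[:, [0]])), index=ids, columns=ids)
        abiotic = pd.DataFrame(z, index=ids, columns=["v0", "v1", "v2"])
        res = bioenv(biotic, abiotic, n_perm=0)
        assert res.best_subset == ("v0",)
        assert res.rho == pytest.approx(1.0)

    def test_matches_naive_enumeration(self):
        from scipy.spatial.distance import squareform
        for seed in range(5):
            biotic, abiotic = self._study(seed)
            res = bioenv(biotic, abiotic, n_perm=0)
            z = ((abiotic - abiotic.mean()) / abiotic.std(ddof=1)).to_numpy()
            cond = squareform(biotic.to_numpy(), checks=False)
            (subset, rho), per_size = naive_bioenv(cond, z, list(abiotic.columns))
            assert res.best_subset == subset
            assert res.rho == pytest.approx(rho)

    def test_matches_skbio_per_size(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import bioenv as sk_bioenv
        biotic, abiotic = self._study(99)
        res = bioenv(biotic, abiotic, n_perm=0)
        dm = DistanceMatrix(biotic.to_numpy(), ids=list(biotic.index))
        sk = sk_bioenv(dm, abiotic)
        for size, (subset, rho) in res.per_size.items():
            row = sk[sk["size"] == size]
            assert set(row.index[0].split(", ")) == set(subset)
            assert row["correlation"].iloc[0] == pytest.approx(rho, abs=1e-9)

    def test_unrelated_abiotics_fall_below_threshold(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(12)]
        d = rng.uniform(1, 2, (12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        biotic = pd.DataFrame(d, index=ids, columns=ids)
        abiotic = pd.DataFrame(rng.normal(size=(12, 3)), index=ids,
                               columns=["x", "y", "z"])
        res = bioenv(biotic, abiotic, n_perm=99, seed=3)
        assert not res.significant

    def test_constant_column_excluded(self):
        biotic, abiotic = self._study(7)
        abiotic["flat"] = 1.0
        res = bioenv(biotic, abiotic, n_perm=0)
        assert all("flat" not in s for s in res.best_subset)


class TestSharedASVs:
    def test_identical_sets(self):
        out = shared_asv_matrix({"A": {"x", "y"}, "B": {"x", "y"}})
        assert out.loc["A", "B"] == pytest.approx(100.0)

    def test_disjoint_sets(self):
        out = shared_asv_matrix({"A": {"x"}, "B": {"y"}})
        assert out.loc["A", "B"] == pytest.approx(0.0)

    def test_union_convention_hand_count(self):
        out = shared_asv_matrix({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert out.loc["A", "B"] == pytest.approx(50.0)

    def test_smaller_set_convention(self):
        out = shared_asv_matrix({"A": {"a", "b", "c"}, "B": {"b", "c"}},
                                convention="smaller")
        assert out.loc["A", "B"] == pytest.approx(100.0)

    def test_diagonal_and_symmetry(self):
        out = shared_asv_matrix({"A": {"a", "b"}, "B": {"b"}, "C": {"c"}})
        assert (np.diag(out) == 100.0).all()
        assert out.equals(out.T)
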