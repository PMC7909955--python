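import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_rand_score

from mbcs import (ConnectivityMatrix, SimilarityMatrix,
                  cosine_similarity_matrix, hierarchical_cluster,
                  input_output_similarity_correlation, mantel_test,
                  pool_by_type, spectral_cluster)
from mbcs.similarity import manhattan_profile_distance


def _profiles(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"n{i}" for i in range(values.shape[0])]
    cols = [f"p{j}" for j in range(values.shape[1])]
    return ConnectivityMatrix(values, ids, cols)


# ---------------------------------------------------------------------------
# cosine similarity
# ---------------------------------------------------------------------------

def test_cosine_analytic_anchors():
    s = cosine_similarity_matrix(_profiles([[2, 2, 0, 0],
                                            [2, 2, 0, 0],
                                            [0, 0, 3, 3],
                                            [0, 2, 2, 0]]))
    assert s.values[0, 1] == pytest.approx(1.0)    # identical profiles
    assert s.values[0, 2] == pytest.approx(0.0)    # disjoint partners
    assert s.values[0, 3] == pytest.approx(0.5)    # half overlap, equal weights
    assert np.allclose(np.diag(s.values), 1.0)


def test_cosine_zero_profile_convention_and_exclusions(caplog):
    with caplog.at_level("WARNING", logger="mbcs"):
        s = cosine_similarity_matrix(_profiles([[1, 1], [0, 0]]))
    assert s.values[1, 1] == 0.0 and s.values[0, 1] == 0.0
    assert "zero profiles" in caplog.text
    # excluding the only shared partner removes the similarity
    m = _profiles([[5, 1, 0], [5, 0, 1]])
    full = cosine_similarity_matrix(m)
    trimmed = cosine_similarity_matrix(m, exclusions=("p0",))
    assert full.values[0, 1] > 0.9
    assert trimmed.values[0, 1] == pytest.approx(0.0)


def test_cosine_invariant_to_per_neuron_rescaling():
    rng = np.random.default_rng(0)
    v = rng.poisson(4, (6, 10)).astype(float) + 0.1
    s1 = cosine_similarity_matrix(_profiles(v))
    s2 = cosine_similarity_matrix(_profiles(v * rng.uniform(0.5, 9, (6, 1))))
    assert np.allclose(s1.values, s2.values, atol=1e-10)


def test_pool_by_type_singletons_and_pairs():
    rng = np.random.default_rng(1)
    s = cosine_similarity_matrix(_profiles(rng.poisson(4, (5, 8)) + 0.0))
    singleton = pool_by_type(s, {i: i for i in s.ids})
    assert np.allclose(singleton.values, s.values)
    pooled = pool_by_type(s, {"n0": "A", "n1": "A", "n2": "B", "n3": "B",
                              "n4": "B"})
    assert pooled.values[0, 0] == pytest.approx(s.values[0, 1])  # 2-cell type
    # brute-force averaging oracle for the cross block
    cross = [s.values[i, j] for i in (0, 1) for j in (2, 3, 4)]
    a, b = list(pooled.ids).index("A"), list(pooled.ids).index("B")
    assert pooled.values[a, b] == pytest.approx(np.mean(cross))


# ---------------------------------------------------------------------------
# spectral clustering
# ---------------------------------------------------------------------------

def _block_profiles(rng, blocks, n_features=30, noise=0.05):
    rows, labels = [], []
    for b, size in enumerate(blocks):
        proto = np.zeros(n_features)
        proto[b * 10:(b + 1) * 10] = 10.0
        for _ in range(size):
            rows.append(proto + rng.uniform(0, noise, n_features))
            labels.append(b)
    return _profiles(np.array(rows)), np.array(labels)


def test_spectral_two_blocks_silhouette_selects_two():
    m, truth = _block_profiles(np.random.default_rng(2), [5, 5])
    res = spectral_cluster(cosine_similarity_matrix(m), seed=0)
    assert res.k == 2
    assert adjusted_rand_score(truth, res.labels) == 1.0


def test_spectral_three_planted_blocks_recovered_exactly():
    m, truth = _block_profiles(np.random.default_rng(3), [4, 6, 5])
    res = spectral_cluster(cosine_similarity_matrix(m), seed=0)
    assert adjusted_rand_score(truth, res.labels) == 1.0


def test_spectral_identical_profiles_degenerate(caplog):
    m = _profiles(np.tile([1.0, 2.0, 3.0], (5, 1)))
    with caplog.at_level("WARNING", logger="mbcs"):
        res = spectral_cluster(cosine_similarity_matrix(m), seed=0)
    assert res.k == 1 and not res.labels.any()


def test_spectral_labels_stable_under_input_permutation():
    rng = np.random.default_rng(4)
    m, truth = _block_profiles(rng, [4, 4, 4])
    s = cosine_similarity_matrix(m)
    res = spectral_cluster(s, k=3, seed=0)
    perm = rng.permutation(len(s.ids))
    s_perm = SimilarityMatrix(tuple(np.array(s.ids)[perm]),
                              s.values[np.ix_(perm, perm)])
    res_perm = spectral_cluster(s_perm, k=3, seed=0)
    assert adjusted_rand_score(res.labels[perm], res_perm.labels) == 1.0


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def test_hierarchical_first_merge_and_cuts():
    d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.0]])
    res = hierarchical_cluster(d, linkage="average")
    assert sorted(res.linkage_matrix[0, :2].astype(int).tolist()) == [0, 1]
    assert len(np.unique(res.cut_height(100.0))) == 1
    assert len(np.unique(res.cut_height(0.5))) == 3
    assert len(np.unique(res.cut_k(2))) == 2


def test_average_linkage_matches_hand_simulated_oracle():
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 5, (8, 2))
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    res = hierarchical_cluster(d, linkage="average")

    # hand-simulated average linkage: merge the closest pair of clusters,
    # with inter-cluster distance = mean of member pair distances
    clusters = {i: [i] for i in range(8)}
    heights = []
    while len(clusters) > 1:
        best = (None, None, np.inf)
        keys = list(clusters)
        for a, b in itertools.combinations(keys, 2):
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if dist < best[2]:
                best = (a, b, dist)
        a, b, h = best
        heights.append(h)
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(a) + clusters.pop(b)
    assert np.allclose(res.linkage_matrix[:, 2], heights, atol=1e-10)
    assert np.all(np.diff(res.linkage_matrix[:, 2]) >= -1e-12)


def test_manhattan_profile_distance_normalises_first():
    m = _profiles([[2, 2], [1, 1], [4, 0]])
    d = manhattan_profile_distance(m)
    assert d[0, 1] == pytest.approx(0.0)       # same input fractions
    assert d[0, 2] == pytest.approx(1.0)       # |0.5-1| + |0.5-0|


def test_non_symmetric_distance_rejected():
    with pytest.raises(ValueError):
        hierarchical_cluster(np.array([[0, 1], [2, 0.0]]))


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _random_distance(rng, n):
    pts = rng.uniform(0, 10, (n, 3))
    return np.linalg.norm(pts[:, None] - pts[None], axis=-1)


def test_mantel_identity_hits_minimum_p():
    d = _random_distance(np.random.default_rng(6), 5)
    res = mantel_test(d, d.copy(), n_perm=10_000)
    assert res.exhaustive and res.n_perm == 120
    assert res.r == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 121)


def test_mantel_constant_matrix_rejected():
    d = _random_distance(np.random.default_rng(7), 5)
    const = np.ones((5, 5)) - np.eye(5)
    with pytest.raises(ValueError, match="variance"):
        mantel_test(d, const)


def test_mantel_matches_exhaustive_enumeration_oracle():
    rng = np.random.default_rng(8)
    d1, d2 = _random_distance(rng, 4), _random_distance(rng, 4)
    res = mantel_test(d1, d2, n_perm=10_000)
    iu = np.triu_indices(4, 1)
    r_obs = pearsonr(d1[iu], d2[iu])[0]
    higher = sum(
        pearsonr(d1[iu], d2[np.ix_(p, p)][iu])[0] > r_obs + 1e-12
        for p in itertools.permutations(range(4)))
    assert res.r == pytest.approx(r_obs)
    assert res.p_value == pytest.approx((1 + higher) / (1 + 24))


def test_mantel_r_agrees_with_independent_reference():
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel
    rng = np.random.default_rng(9)
    d1, d2 = _random_distance(rng, 9), _random_distance(rng, 9)
    res = mantel_test(d1, d2, n_perm=2000, rng=np.random.default_rng(0))
    r_ref, p_ref, _ = skbio_mantel(DistanceMatrix(d1), DistanceMatrix(d2),
                                   permutations=2000, alternative="greater")
    assert res.r == pytest.approx(r_ref, abs=1e-12)
    assert res.p_value == pytest.approx(p_ref, abs=0.05)


def test_mantel_r_invariant_under_joint_permutation():
    rng = np.random.default_rng(10)
    d1, d2 = _random_distance(rng, 6), _random_distance(rng, 6)
    r0 = mantel_test(d1, d2, n_perm=10).r
    perm = rng.permutation(6)
    r1 = mantel_test(d1[np.ix_(perm, perm)], d2[np.ix_(perm, perm)], n_perm=10).r
    assert r0 == pytest.approx(r1)


# ---------------------------------------------------------------------------
# input/output similarity correlation
# ---------------------------------------------------------------------------

def _sim(values, ids):
    return SimilarityMatrix(ids, np.asarray(values, dtype=float))


def test_identical_pair_vectors_give_correlation_one():
    rng = np.random.default_rng(11)
    v = rng.uniform(0, 1, (6, 6))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    ids = tuple("abcdef")
    r, p = input_output_similarity_correlation(_sim(v, ids), _sim(v.copy(), ids),
                                               n_perm=500,
                                               rng=np.random.default_rng(0))
    assert r == pytest.approx(1.0)
    assert p < 0.05


def test_independent_structures_are_not_significant_too_often():
    rng = np.random.default_rng(12)
    ids = tuple("abcdefgh")
    rejections = 0
    n_rep = 40
    for _ in range(n_rep):
        def rand_sim():
            v = rng.uniform(0, 1, (8, 8))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            return _sim(v, ids)
        _, p = input_output_similarity_correlation(rand_sim(), rand_sim(),
                                                   n_perm=200, rng=rng)
        rejections += p <= 0.1
    assert rejections / n_rep <= 0.25   # ≈ alpha with binomial slack


def test_shared_compartment_grouping_detected():
    # both matrices share the same two-block compartment structure
    rng = np.random.default_rng(13)
    ids = tuple("abcdefgh")
    block = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    base = (block[:, None] == block[None]).astype(float)

    def noisy():
        v = 0.8 * base + 0.1 + rng.uniform(0, 0.05, (8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        return _sim(v, ids)

    r, p = input_output_similarity_correlation(noisy(), noisy(), n_perm=1000,
                                               rng=np.random.default_rng(1))
    assert r > 0.8 and p < 0.05
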