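"""Connectivity-similarity analyses: cosine matrices, clustering, Mantel tests.

Cosine similarity between the input (or output) synapse-count profiles of two
neurons is 1 when they contact the same partners with the same relative
strengths and 0 when they share no partners; it weights strong connections
more without an arbitrary cutoff.  On top of cosine matrices this module
provides spectral clustering with silhouette-selected cluster number,
hierarchical clustering of connectivity profiles (average or Ward linkage,
Manhattan distances on input fractions when requested), type-level pooling of
cell-level similarities, the Mantel permutation test of correlation between
two distance matrices (exhaustive for small n), and the compartment-level
correlation between DAN-input similarity and MBON-output similarity.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.cluster import SpectralClustering
from sklearn.metrics import silhouette_score
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .core import ConnectivityMatrix

logger = logging.getLogger("mbcs")


# ---------------------------------------------------------------------------
# cosine similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityMatrix:
    ids: tuple
    values: np.ndarray
    basis: str = "inputs"            # or "outputs"
    exclusions: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        if v.shape != (len(self.ids),) * 2:
            raise ValueError("similarity matrix must be square over ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def cosine_similarity_matrix(profiles: ConnectivityMatrix, basis: str = "inputs",
                             exclusions=()) -> SimilarityMatrix:
    """Pairwise cosine similarity of row profiles.

    Each row of ``profiles`` is one neuron's partner profile (columns are
    partners); ``exclusions`` names partner columns dropped before
    normalisation (e.g. KC/APL/DPM input when comparing DANs).  Zero
    profiles get similarity 0 to everything — including themselves — by
    convention, with a warning.
    """
    keep = [j for j, cid in enumerate(profiles.col_ids) if cid not in set(exclusions)]
    v = profiles.values[:, keep]
    sim = _sk_cosine(v)
    zero = ~v.any(axis=1)
    if zero.any():
        logger.warning("cosine_similarity_matrix: %d zero profiles set to 0",
                       int(zero.sum()))
        sim[zero, :] = 0.0
        sim[:, zero] = 0.0
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(profiles.row_ids, sim, basis, tuple(exclusions))


def pool_by_type(s: SimilarityMatrix, type_map: dict) -> SimilarityMatrix:
    """Average cell-level similarities into a type-level matrix.

    Entry (T1, T2) is the mean over cell pairs i∈T1, j∈T2 with i≠j when
    T1=T2; singleton types reproduce the cell-level values exactly.
    """
    missing = [i for i in s.ids if i not in type_map]
    if missing:
        raise ValueError(f"ids without a type: {missing}")
    types = list(dict.fromkeys(type_map[i] for i in s.ids))
    members = {t: [k for k, i in enumerate(s.ids) if type_map[i] == t] for t in types}
    out = np.zeros((len(types), len(types)))
    for a, t1 in enumerate(types):
        for b, t2 in enumerate(types):
            vals = [s.values[i, j] for i in members[t1] for j in members[t2]
                    if not (t1 == t2 and i == j)]
            if not vals:  # a singleton type with itself: similarity of the cell
                vals = [s.values[members[t1][0], members[t1][0]]]
            out[a, b] = np.mean(vals)
    out = (out + out.T) / 2.0
    return SimilarityMatrix(types, out, s.basis, s.exclusions)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    ids: tuple
    silhouette_trace: dict | None = None     # candidate k -> score
    linkage_matrix: np.ndarray | None = None
    linkage_method: str | None = None
    seed: int | None = None

    def cut_k(self, k: int) -> np.ndarray:
        if self.linkage_matrix is None:
            raise ValueError("no dendrogram stored")
        return hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust") - 1

    def cut_height(self, height: float) -> np.ndarray:
        if self.linkage_matrix is None:
            raise ValueError("no dendrogram stored")
        return hierarchy.fcluster(self.linkage_matrix, t=height,
                                  criterion="distance") - 1


def spectral_cluster(s: SimilarityMatrix, k: int | None = None,
                     k_range=range(2, 11), seed: int | None = 0
                     ) -> ClusteringResult:
    """Spectral clustering on a cosine-similarity affinity.

    Negative similarities are clipped at 0.  When ``k`` is not given it is
    selected by the best silhouette score (computed on distance 1 − cosine)
    over ``k_range``.  Degenerate inputs where all profiles are identical
    return a single cluster with a warning.
    """
    n = len(s.ids)
    affinity = np.clip(s.values, 0.0, None)
    dist = np.clip(1.0 - s.values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    if np.allclose(dist, 0.0, atol=1e-12):
        logger.warning("spectral_cluster: all profiles identical; returning k=1")
        return ClusteringResult(np.zeros(n, dtype=int), 1, s.ids, None, seed=seed)

    def run(kk):
        model = SpectralClustering(n_clusters=kk, affinity="precomputed",
                                   random_state=seed)
        return model.fit_predict(affinity)

    if k is not None:
        if k > n:
            raise ValueError("fewer items than clusters")
        return ClusteringResult(run(k), k, s.ids, None, seed=seed)

    trace = {}
    best_k, best_labels, best_score = None, None, -np.inf
    for kk in k_range:
        if kk >= n:
            continue
        labels = run(kk)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dist, labels, metric="precomputed")
        trace[kk] = float(score)
        if score > best_score:
            best_k, best_labels, best_score = kk, labels, score
    if best_k is None:
        raise ValueError("no candidate k produced a valid clustering")
    return ClusteringResult(best_labels, best_k, s.ids, trace, seed=seed)


def hierarchical_cluster(d, linkage: str = "average", ids=None,
                         default_k: int | None = None) -> ClusteringResult:
    """Agglomerative clustering of a symmetric distance matrix.

    ``linkage`` is "average" (used with morphology-similarity distances) or
    "ward" (used with Manhattan distances between input-fraction profiles;
    see :func:`manhattan_profile_distance`).  The full dendrogram is kept so
    callers can cut at a height or at a cluster count.
    """
    d = d.values if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if linkage not in ("average", "ward"):
        raise ValueError("linkage must be 'average' or 'ward'")
    if ids is None:
        ids = tuple(range(d.shape[0]))
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    k = default_k if default_k is not None else 1
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust") - 1
    return ClusteringResult(labels, int(labels.max()) + 1, tuple(ids),
                            linkage_matrix=z, linkage_method=linkage)


def manhattan_profile_distance(profiles: ConnectivityMatrix,
                               normalize: bool = True) -> np.ndarray:
    """Manhattan distances between per-neuron connectivity profiles.

    When ``normalize`` is set each row profile is first divided by its sum
    (input-fraction normalisation per neuron), matching the preprocessing
    used before Ward clustering of DAN upstream profiles.
    """
    v = profiles.values.astype(float)
    if normalize:
        sums = v.sum(axis=1, keepdims=True)
        v = np.divide(v, np.where(sums == 0, 1.0, sums))
    return squareform(pdist(v, metric="cityblock"))


# ---------------------------------------------------------------------------
# Mantel test and related permutation machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    exhaustive: bool


def _upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel_test(d1, d2, n_perm: int = 100_000,
                exhaustive_if_feasible: bool = True,
                rng: np.random.Generator | None = None) -> MantelResult:
    """Permutation test of the Pearson correlation of two distance matrices.

    The statistic is r over the upper-triangle vectors; the null jointly
    permutes rows and columns of ``d2``.  All n! permutations are enumerated
    when that is no more work than ``n_perm`` random draws; p uses the
    add-one estimator with a strict "higher-than" count,
    (1 + #{r_perm > r_obs}) / (1 + #perms).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n = d1.shape[0]
    if d1.shape != d2.shape or d1.shape != (n, n):
        raise ValueError("distance matrices must be square and same shape")
    if n < 4:
        raise ValueError("need at least 4 items for a meaningful test")
    v1 = _upper(d1)
    if np.std(v1) == 0 or np.std(_upper(d2)) == 0:
        raise ValueError("zero-variance distance vector")
    r_obs = float(pearsonr(v1, _upper(d2))[0])

    def r_of(perm):
        return float(pearsonr(v1, _upper(d2[np.ix_(perm, perm)]))[0])

    exhaustive = exhaustive_if_feasible and math.factorial(n) <= n_perm
    higher = 0
    if exhaustive:
        count = 0
        for perm in itertools.permutations(range(n)):
            count += 1
            if r_of(np.asarray(perm)) > r_obs + 1e-12:
                higher += 1
        total = count
    else:
        if rng is None:
            rng = np.random.default_rng()
        for _ in range(n_perm):
            if r_of(rng.permutation(n)) > r_obs + 1e-12:
                higher += 1
        total = n_perm
    return MantelResult(r_obs, (1.0 + higher) / (1.0 + total), total, exhaustive)


def input_output_similarity_correlation(dan_input_sim: SimilarityMatrix,
                                        mbon_output_sim: SimilarityMatrix,
                                        n_perm: int = 10_000,
                                        rng: np.random.Generator | None = None):
    """Correlation between compartment-pair input and output similarities.

    Both arguments are compartment-level similarity matrices over the same
    compartments (e.g. pooled DAN-input similarity vs pooled MBON-output
    similarity).  Returns ``(r, p)`` where r is the Pearson correlation over
    compartment pairs and p comes from jointly permuting the compartment
    labels of one matrix (Mantel-style, strict ">", add-one estimator).
    """
    if dan_input_sim.ids != mbon_output_sim.ids:
        raise ValueError("similarity matrices must index the same compartments")
    n = len(dan_input_sim.ids)
    if n * (n - 1) // 2 < 3:
        raise ValueError("need at least 3 compartment pairs")
    if rng is None:
        rng = np.random.default_rng()
    a, b = dan_input_sim.values, mbon_output_sim.values
    va = _upper(a)
    if np.std(va) == 0 or np.std(_upper(b)) == 0:
        raise ValueError("zero-variance similarity vector")
    r_obs = float(pearsonr(va, _upper(b))[0])
    higher = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if float(pearsonr(va, _upper(b[np.ix_(perm, perm)]))[0]) > r_obs + 1e-12:
            higher += 1
    return r_obs, (1.0 + higher) / (1.0 + n_perm)
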