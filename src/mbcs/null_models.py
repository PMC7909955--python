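"""Shuffle null models and permutation tests for wiring structure.

Three detectors are implemented:

* **Degree-preserving PN→KC shuffles with PCA envelopes.**  Each row (KC) of
  a binary connection matrix keeps its degree but resamples its partners
  without replacement, with probability proportional to the original column
  sums — the random-wiring model in which KCs sample uPNs in proportion to
  the total number of connections each uPN makes.  Principal-component
  variance fractions of the observed matrix are compared against percentile
  envelopes over shuffles; components above the upper bound indicate
  structure inconsistent with random sampling.

* **Weighted-sampling convergence null.**  Observed counts of how many
  distinct MBON types feed each downstream neuron (at a synapse threshold)
  are compared against a null in which every MBON's output synapses are
  multinomially reassigned to candidate targets with probability
  proportional to each candidate's total input synapses.

* **Nearest-neighbour subtype permutation test.**  For each synapse the
  nearest synapse belonging to a *different* neuron is found; the fraction of
  same-subtype nearest neighbours is tested against a null that permutes the
  neuron→subtype labelling (neurons, not synapses, are the exchangeable
  units).

All permutation p-values use the add-one estimator (1 + #extreme)/(1 + n) and
all stochastic operations are reproducible given a seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Connectome, ConnectivityMatrix

logger = logging.getLogger("mbcs")


# ---------------------------------------------------------------------------
# degree-preserving shuffles and PCA envelopes
# ---------------------------------------------------------------------------

def shuffle_degree_preserving(b: ConnectivityMatrix,
                              rng: np.random.Generator) -> ConnectivityMatrix:
    """Resample each row's partners ∝ original column sums, degree fixed.

    Rows keep their exact degree; columns are drawn without replacement with
    probability weights proportional to the original column sums, so the
    expected column marginals (average connection probability per uPN) are
    retained but no other structure is.
    """
    if b.normalized != "binary":
        raise ValueError("shuffle expects a binary matrix")
    values = b.values
    col_w = values.sum(axis=0)
    if col_w.sum() == 0:
        raise ValueError("matrix has no connections")
    p = col_w / col_w.sum()
    n_avail = int((col_w > 0).sum())
    out = np.zeros_like(values)
    n_cols = values.shape[1]
    for i, row in enumerate(values):
        k = int(row.sum())
        if k == 0:
            continue
        if k > n_avail:
            raise ValueError(f"row {b.row_ids[i]!r} degree {k} exceeds the "
                             f"{n_avail} available columns")
        cols = rng.choice(n_cols, size=k, replace=False, p=p)
        out[i, cols] = 1.0
    return ConnectivityMatrix(out, b.row_ids, b.col_ids, "binary")


def pca_variance_spectrum(b: ConnectivityMatrix, center: str = "columns"
                          ) -> np.ndarray:
    """Ordered fractions of variance explained by the principal components.

    Rows are observations (KCs), columns variables (uPNs); the covariance is
    computed after centering each column (``center="rows"`` transposes the
    convention).  Returns a vector of length n_variables, descending,
    summing to 1.
    """
    x = b.values
    if x.shape[0] < 2:
        raise ValueError("need at least two rows")
    if center == "rows":
        x = x.T
    elif center != "columns":
        raise ValueError("center must be 'columns' or 'rows'")
    centered = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(centered, compute_uv=False)
    lam = np.zeros(x.shape[1])
    lam[:len(s)] = s ** 2
    total = lam.sum()
    if total == 0:
        raise ValueError("constant matrix: zero total variance")
    return np.sort(lam / total)[::-1]


@dataclass(frozen=True)
class ShuffleEnsemble:
    """Observed PCA spectrum against a degree-preserving shuffle ensemble."""

    observed: np.ndarray
    samples: np.ndarray          # (n_shuffles, n_components)
    lower: np.ndarray
    upper: np.ndarray
    level: float
    flags_above: np.ndarray      # observed above the upper bound (structure)
    flags_outside: np.ndarray    # outside the two-sided envelope (calibration)

    @property
    def n_shuffles(self) -> int:
        return self.samples.shape[0]


def shuffle_envelope(b: ConnectivityMatrix, n_shuffles: int = 1000,
                     level: float = 0.95,
                     rng: np.random.Generator | None = None,
                     center: str = "columns",
                     observed: ConnectivityMatrix | None = None) -> ShuffleEnsemble:
    """Percentile envelope of shuffled PCA spectra, with per-component flags.

    The envelope covers the central ``level`` mass of each component's
    variance fraction over shuffles of ``b``.  ``flags_above`` marks
    components whose observed fraction exceeds the upper bound — deviations
    in the first few components indicate structure inconsistent with the
    random model.  By default the observed spectrum is that of ``b`` itself;
    passing ``observed`` compares a different matrix against the envelope
    (used for type-I calibration, where the observed matrix is one more
    shuffle draw of the same base and is therefore exchangeable with the
    envelope samples).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    if n_shuffles == 1:
        logger.warning("shuffle_envelope: n_shuffles=1 gives a degenerate envelope")
    observed = pca_variance_spectrum(b if observed is None else observed,
                                     center=center)
    samples = np.empty((n_shuffles, len(observed)))
    for s in range(n_shuffles):
        samples[s] = pca_variance_spectrum(
            shuffle_degree_preserving(b, rng), center=center)
    alpha = (1.0 - level) / 2.0
    lower = np.percentile(samples, 100 * alpha, axis=0)
    upper = np.percentile(samples, 100 * (1 - alpha), axis=0)
    return ShuffleEnsemble(
        observed, samples, lower, upper, level,
        flags_above=observed > upper,
        flags_outside=(observed > upper) | (observed < lower),
    )


# ---------------------------------------------------------------------------
# MBON convergence and its weighted-sampling null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvergenceResult:
    per_target: pd.Series        # target id -> number of MBON types ≥ threshold
    histogram: pd.Series         # #types -> #targets
    n_targets: int
    frac_multi: float            # fraction of targets with ≥ 2 types


def mbon_convergence(c: Connectome, threshold: int = 10) -> ConvergenceResult:
    """How many distinct MBON cell types feed each downstream neuron.

    A target counts an MBON type when the summed synapses from cells of that
    type reach the threshold (default 10).  MBONs themselves may be targets
    of other MBON types.
    """
    mbons = c.neurons[c.neurons["super_class"] == "MBON"]
    if mbons.empty:
        raise ValueError("no annotated MBONs")
    e = c.edges[c.edges["pre_id"].isin(mbons.index)].copy()
    e["mbon_type"] = e["pre_id"].map(mbons["cell_type"])
    by_type = e.groupby(["post_id", "mbon_type"])["weight"].sum()
    strong = by_type[by_type >= threshold]
    per_target = strong.groupby("post_id").size().astype(int)
    per_target = per_target.sort_index()
    hist = per_target.value_counts().sort_index()
    n_targets = int(len(per_target))
    frac_multi = float((per_target >= 2).mean()) if n_targets else 0.0
    return ConvergenceResult(per_target, hist, n_targets, frac_multi)


@dataclass(frozen=True)
class ConvergenceNull:
    n_targets: np.ndarray        # per draw
    frac_multi: np.ndarray       # per draw
    n_targets_mean: float
    frac_multi_mean: float
    n_targets_interval: tuple
    frac_multi_interval: tuple


def convergence_null(c: Connectome, threshold: int = 10, n_draws: int = 100,
                     rng: np.random.Generator | None = None,
                     level: float = 0.95) -> ConvergenceNull:
    """Null in which MBON outputs are resampled ∝ candidate input synapses.

    Per draw, each MBON cell's total output synapse count is conserved and
    reassigned multinomially over candidate targets (all non-MBON neurons
    with at least one input synapse) with probabilities proportional to
    their total input synapse counts; the same thresholded type counting is
    then applied.
    """
    if rng is None:
        rng = np.random.default_rng()
    mbons = c.neurons[c.neurons["super_class"] == "MBON"]
    mbon_ids = list(mbons.index)
    e = c.edges
    out_totals = (e[e["pre_id"].isin(mbon_ids)]
                  .groupby("pre_id")["weight"].sum().reindex(mbon_ids, fill_value=0))
    in_totals = e.groupby("post_id")["weight"].sum()
    candidates = [nid for nid in c.neurons.index
                  if nid not in set(mbon_ids) and in_totals.get(nid, 0) > 0]
    if not candidates:
        raise ValueError("no candidate targets with input synapses")
    p = in_totals.reindex(candidates).to_numpy(dtype=float)
    p = p / p.sum()

    types = mbons["cell_type"]
    uniq_types = list(dict.fromkeys(types))
    type_idx = {t: i for i, t in enumerate(uniq_types)}

    n_targets = np.zeros(n_draws)
    frac_multi = np.zeros(n_draws)
    for d in range(n_draws):
        counts = np.zeros((len(uniq_types), len(candidates)), dtype=np.int64)
        for mid in mbon_ids:
            total = int(out_totals[mid])
            if total == 0:
                continue
            counts[type_idx[types[mid]]] += rng.multinomial(total, p)
        per_target = (counts >= threshold).sum(axis=0)
        hit = per_target > 0
        n_targets[d] = int(hit.sum())
        frac_multi[d] = float((per_target[hit] >= 2).mean()) if hit.any() else 0.0
    alpha = (1 - level) / 2
    return ConvergenceNull(
        n_targets, frac_multi, float(n_targets.mean()), float(frac_multi.mean()),
        tuple(np.percentile(n_targets, [100 * alpha, 100 * (1 - alpha)])),
        tuple(np.percentile(frac_multi, [100 * alpha, 100 * (1 - alpha)])),
    )


# ---------------------------------------------------------------------------
# nearest-neighbour subtype permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationTestResult:
    observed: float
    null_samples: np.ndarray
    p_value: float
    n_perm: int


def nn_subtype_test(sites: pd.DataFrame, n_perm: int = 10000,
                    rng: np.random.Generator | None = None):
    """Do nearest-neighbour synapses share the subtype of their owner?

    ``sites`` needs columns ``neuron_id``, ``subtype``, ``x``, ``y``, ``z``
    (subtype constant within a neuron).  For each synapse the nearest
    (Euclidean) synapse belonging to a different neuron is recorded; the
    statistic is the fraction of same-subtype nearest neighbours.  The null
    permutes subtype labels across neurons and the p-value is
    (1 + #{null ≥ observed}) / (1 + n_perm).  Returns ``(contingency_table,
    PermutationTestResult)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    neurons = sites["neuron_id"].to_numpy()
    uniq_neurons, neuron_idx = np.unique(neurons, return_inverse=True)
    if len(uniq_neurons) < 2:
        raise ValueError("need synapses from at least two neurons")
    subtype_of_neuron = (sites.groupby("neuron_id")["subtype"].first()
                         .reindex(uniq_neurons).to_numpy())
    if len(np.unique(subtype_of_neuron)) < 2:
        raise ValueError("need at least two subtypes")

    xyz = sites[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(xyz)
    n = len(xyz)
    neighbor_neuron = np.full(n, -1)
    k = min(n, 12)
    pending = np.arange(n)
    while len(pending):
        _, idx = tree.query(xyz[pending], k=k)
        idx = np.atleast_2d(idx)
        still = []
        for row, i in enumerate(pending):
            hits = idx[row][neuron_idx[idx[row]] != neuron_idx[i]]
            if len(hits):
                neighbor_neuron[i] = neuron_idx[hits[0]]
            else:
                still.append(i)
        pending = np.array(still, dtype=int)
        if len(pending) and k == n:
            raise ValueError("a synapse has no admissible neighbour")
        k = min(n, k * 2)

    def statistic(labels_of_neuron):
        own = labels_of_neuron[neuron_idx]
        nb = labels_of_neuron[neighbor_neuron]
        return float(np.mean(own == nb))

    observed = statistic(subtype_of_neuron)
    table = pd.crosstab(
        pd.Series(subtype_of_neuron[neuron_idx], name="own_subtype"),
        pd.Series(subtype_of_neuron[neighbor_neuron], name="neighbor_subtype"))

    null = np.empty(n_perm)
    for s in range(n_perm):
        null[s] = statistic(rng.permutation(subtype_of_neuron))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return table, PermutationTestResult(observed, null, float(p), n_perm)
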