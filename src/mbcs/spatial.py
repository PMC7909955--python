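"""Spatial statistics of the mushroom-body calyx.

Projection-neuron axons terminate in synaptic boutons inside the calyx, each
wrapped by the claw of a Kenyon cell dendrite.  This module detects boutons by
spatial clustering of PN output synapses, summarises their spatial
organisation (pairwise-distance histograms split by glomerulus, neighbour
counts within a radius), builds radius-constrained shuffles of the claw→bouton
assignment, and quantifies the consequences for the KC representation through
the participation ratio of the PN→KC weight matrix and the dimension of a
sparse-coding model of KC activity.  A separate utility measures how quickly
a KC fibre's spatial neighbourhood turns over along the parallel-fibre axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform

from .core import ConnectivityMatrix

logger = logging.getLogger("mbcs")

BOUTON_COLUMNS = ("bouton_id", "pn_id", "glomerulus", "x", "y", "z")
CLAW_COLUMNS = ("kc_id", "bouton_id", "anchor_x", "anchor_y", "anchor_z", "n_synapses")


@dataclass
class CalyxGeometry:
    """Bouton centroids and claw→bouton assignments in 3D calyx space.

    ``boutons`` is indexed by ``bouton_id`` with columns ``pn_id``,
    ``glomerulus``, ``x``, ``y``, ``z`` (µm); ``claws`` has one row per KC
    claw with its anchor position, assigned bouton, and synapse count.
    """

    boutons: pd.DataFrame
    claws: pd.DataFrame

    def __post_init__(self):
        if self.boutons.index.name != "bouton_id":
            if "bouton_id" in self.boutons.columns:
                self.boutons = self.boutons.set_index("bouton_id")
            else:
                self.boutons = self.boutons.rename_axis("bouton_id")
        missing = set(self.claws["bouton_id"]) - set(self.boutons.index)
        if missing:
            raise ValueError(f"claws reference absent boutons: {sorted(map(str, missing))}")

    def bouton_xyz(self) -> np.ndarray:
        return self.boutons[["x", "y", "z"]].to_numpy(dtype=float)

    def claw_counts(self) -> pd.Series:
        return self.claws.groupby("kc_id").size()


# ---------------------------------------------------------------------------
# bouton detection and descriptive spatial statistics
# ---------------------------------------------------------------------------

def detect_boutons(sites: pd.DataFrame, link_distance: float = 2.5) -> pd.DataFrame:
    """Detect bouton centroids by single-linkage clustering of PN synapses.

    ``sites`` needs columns ``pre_id`` (the PN), ``x_um``, ``y_um``, ``z_um``
    and optionally ``glomerulus``.  Within each PN, synapse positions are
    agglomerated by single linkage and the tree is cut at ``link_distance``
    (µm, default 2.5); each cluster's centroid is one bouton.  Deterministic.
    Returns a bouton table in :class:`CalyxGeometry` layout.
    """
    rows = []
    counter = 0
    for pn_id, group in sites.groupby("pre_id", sort=True):
        xyz = group[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if len(xyz) == 1:
            labels = np.array([1])
        else:
            labels = fcluster(linkage(xyz, method="single"),
                              t=link_distance, criterion="distance")
        glom = group["glomerulus"].iloc[0] if "glomerulus" in group.columns else None
        for lab in np.unique(labels):
            centroid = xyz[labels == lab].mean(axis=0)
            rows.append({"bouton_id": f"B{counter:05d}", "pn_id": pn_id,
                         "glomerulus": glom, "x": centroid[0], "y": centroid[1],
                         "z": centroid[2],
                         "n_synapses": int((labels == lab).sum())})
            counter += 1
    return pd.DataFrame(rows).set_index("bouton_id")


def bouton_distance_histograms(g: CalyxGeometry, bins=None):
    """Pairwise bouton-centroid distances split by glomerulus identity.

    Returns ``(same_hist, diff_hist, bin_edges)`` where each histogram counts
    unordered centroid pairs whose PNs come from the same vs different
    glomeruli.  Raw distances are available via :func:`bouton_pair_distances`.
    """
    same, diff = bouton_pair_distances(g)
    if bins is None:
        upper = max(same.max() if same.size else 0.0,
                    diff.max() if diff.size else 0.0, 1.0)
        bins = np.linspace(0.0, upper, 31)
    same_hist, edges = np.histogram(same, bins=bins)
    diff_hist, _ = np.histogram(diff, bins=edges)
    return same_hist, diff_hist, edges


def bouton_pair_distances(g: CalyxGeometry):
    """Raw same-/different-glomerulus pairwise centroid distances."""
    if len(g.boutons) < 2:
        raise ValueError("need at least two boutons")
    d = pdist(g.bouton_xyz())
    glom = g.boutons["glomerulus"].to_numpy()
    same_mask = squareform(glom[:, None] == glom[None, :], checks=False).astype(bool)
    return d[same_mask], d[~same_mask]


def neighbors_within_radius(g: CalyxGeometry, radii: Sequence[float]) -> np.ndarray:
    """Mean number of *other* boutons within each radius of a bouton centroid."""
    if len(g.boutons) < 2:
        raise ValueError("need at least two boutons")
    d = squareform(pdist(g.bouton_xyz()))
    np.fill_diagonal(d, np.inf)
    return np.array([(d <= r).sum(axis=1).mean() for r in radii])


# ---------------------------------------------------------------------------
# radius-constrained shuffles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadiusShuffleConfig:
    r: float
    n_shuffles: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.r < 0:
            raise ValueError("radius must be >= 0")


def radius_shuffle(g: CalyxGeometry, cfg: RadiusShuffleConfig,
                   rng: np.random.Generator | None = None) -> CalyxGeometry:
    """Reassign each claw uniformly among boutons within radius r of its own.

    Eligibility is measured between bouton centroids (a claw inherits its
    bouton's centroid), the original bouton is always eligible, and per-KC
    claw counts are preserved.  ``r = 0`` returns the identity assignment:
    large-scale organisation above r is kept, organisation below r is
    randomised.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    xyz = g.bouton_xyz()
    index = {b: i for i, b in enumerate(g.boutons.index)}
    new_claws = g.claws.copy()
    if cfg.r == 0:
        return CalyxGeometry(g.boutons.copy(), new_claws)
    d = cdist(xyz, xyz)
    eligible = [np.flatnonzero(d[i] <= cfg.r) for i in range(len(xyz))]
    ids = np.asarray(g.boutons.index)
    choices = [
        ids[rng.choice(eligible[index[b]])] for b in g.claws["bouton_id"]
    ]
    new_claws["bouton_id"] = choices
    return CalyxGeometry(g.boutons.copy(), new_claws)


def weights_from_geometry(g: CalyxGeometry,
                          synapse_weighted: bool = True) -> ConnectivityMatrix:
    """PN→KC weight matrix (KC rows × PN columns) implied by a claw assignment."""
    claws = g.claws.join(g.boutons["pn_id"], on="bouton_id")
    kc_ids = sorted(claws["kc_id"].unique())
    pn_ids = sorted(g.boutons["pn_id"].unique())
    ri = {k: i for i, k in enumerate(kc_ids)}
    ci = {p: i for i, p in enumerate(pn_ids)}
    values = np.zeros((len(kc_ids), len(pn_ids)))
    w = claws["n_synapses"] if synapse_weighted and "n_synapses" in claws else 1
    if np.isscalar(w):
        w = np.ones(len(claws))
    for kc, pn, weight in zip(claws["kc_id"], claws["pn_id"], w):
        values[ri[kc], ci[pn]] += weight
    return ConnectivityMatrix(values, kc_ids, pn_ids, "counts")


# ---------------------------------------------------------------------------
# participation ratio and sparse-coding dimension
# ---------------------------------------------------------------------------

def participation_ratio(w) -> float:
    """(Σw)² / Σw² — the effective number of entries carrying the mass of w.

    Equals N for a uniform non-negative vector of length N and 1 for a
    one-hot vector.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero weight vector")
    return float(total ** 2 / np.sum(w ** 2))


def glomerulus_weight_vector(weights: ConnectivityMatrix,
                             glomerulus_of_pn: dict) -> np.ndarray:
    """Collapse a KC×PN weight matrix to per-glomerulus total weights."""
    glom = [glomerulus_of_pn[p] for p in weights.col_ids]
    uniq = list(dict.fromkeys(glom))
    col_sums = weights.values.sum(axis=0)
    return np.array([col_sums[[g == u for g in glom]].sum() for u in uniq])


@dataclass(frozen=True)
class DimensionModelConfig:
    """Monte-Carlo model of sparse KC responses to random PN patterns.

    ``coding_level`` f is the fraction of KCs active per pattern; the KC
    threshold is a single global value calibrated so the mean active
    fraction over sampled patterns equals f.  ``pn_activity`` is "normal"
    (i.i.d. standard normal PN rates) or "bernoulli" (0/1 with rate
    ``pn_rate``).  ``threshold=False`` gives the linear (unthresholded)
    model, used for analytic checks.
    """

    n_patterns: int = 500
    pn_activity: str = "normal"
    pn_rate: float = 0.5
    coding_level: float = 0.05
    threshold: bool = True
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.coding_level < 1:
            raise ValueError("coding level must be in (0, 1)")


@dataclass(frozen=True)
class SpectrumResult:
    eigenvalues: np.ndarray  # descending
    statistic: float  # participation ratio of the spectrum = dimension


def kc_dimension(weights, cfg: DimensionModelConfig,
                 rng: np.random.Generator | None = None) -> SpectrumResult:
    """Dimension of the KC representation under random PN activation.

    Random PN patterns are drawn, KC drives are ``W x``, and KCs above a
    global threshold (calibrated to the coding level f) are active.  The
    dimension is the participation ratio (Σλ)²/Σλ² of the eigenvalues of the
    KC activity covariance estimated over patterns — the quantity that
    governs how well a linear readout of KC activity can discriminate
    random input patterns.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    w = weights.values if isinstance(weights, ConnectivityMatrix) else np.asarray(weights, float)
    n_kc, n_pn = w.shape
    silent = ~w.any(axis=1)
    if silent.any():
        logger.warning("kc_dimension: %d all-zero KC rows stay silent", int(silent.sum()))
    if cfg.pn_activity == "normal":
        x = rng.standard_normal((n_pn, cfg.n_patterns))
    elif cfg.pn_activity == "bernoulli":
        x = (rng.random((n_pn, cfg.n_patterns)) < cfg.pn_rate).astype(float)
    else:
        raise ValueError(f"unknown pn_activity {cfg.pn_activity!r}")
    drive = w @ x
    if cfg.threshold:
        theta = np.quantile(drive, 1.0 - cfg.coding_level)
        activity = (drive > theta).astype(float)
    else:
        activity = drive
    centered = activity - activity.mean(axis=1, keepdims=True)
    s = np.linalg.svd(centered, compute_uv=False)
    lam = s ** 2 / (cfg.n_patterns - 1)
    lam = np.sort(lam)[::-1]
    lam[lam < 0] = 0.0
    if lam.sum() == 0:
        raise ValueError("degenerate activity: zero variance")
    return SpectrumResult(lam, float(lam.sum() ** 2 / np.sum(lam ** 2)))


# ---------------------------------------------------------------------------
# KC fibre neighbour turnover
# ---------------------------------------------------------------------------

def neighbor_change_rate(tracks: np.ndarray, k: int = 10) -> np.ndarray:
    """Fraction of k nearest fibres that change between consecutive steps.

    ``tracks`` has shape (n_fibers, n_steps, 3): per-fibre positions sampled
    on a common arc-length grid (5 µm steps in the original analysis).  At
    each step the k nearest other fibres (Euclidean, same step index) are
    compared with the previous step; the rate is |set difference| / k.
    Returns an (n_fibers, n_steps − 1) array.
    """
    tracks = np.asarray(tracks, dtype=float)
    n_fibers, n_steps, _ = tracks.shape
    if k >= n_fibers:
        raise ValueError("k must be smaller than the number of other fibres")

    def knn_sets(step):
        d = cdist(tracks[:, step], tracks[:, step])
        np.fill_diagonal(d, np.inf)
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        return [set(row) for row in order]

    rates = np.zeros((n_fibers, n_steps - 1))
    prev = knn_sets(0)
    for step in range(1, n_steps):
        cur = knn_sets(step)
        for i in range(n_fibers):
            rates[i, step - 1] = len(cur[i] - prev[i]) / k
        prev = cur
    return rates
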