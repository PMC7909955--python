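"""Data model and shared operations for annotated synaptic connectivity.

The central container is :class:`Connectome`: a neuron table (cell type,
super-class, sensory modality, lobe-compartment annotations), a weighted edge
list (synapse counts, optionally split by postsynaptic site class), and an
optional synapse-site table with 3D positions in micrometres.  On top of it
this module provides the matrix operations every downstream analysis shares:

* rectangular synapse-count matrices between neuron sets (:func:`to_matrix`),
* binarisation at a synapse threshold and input-fraction normalisation,
* two-step ("one-hop") effective connectivity via matrix products of
  input-fraction matrices,
* sensory-modality input fractions per Kenyon cell, KC type, or output neuron,
  and the grouping of KCs into modality streams,
* classification of MBON→DAN feedback into same-compartment ("self") vs
  cross-compartment motifs,
* ECDFs of synapse distance from the root of a dendritic tree (SWC skeletons).

Neuron and compartment names are ASCII transliterations of the usual Greek
labels (``KCgm`` for the main γ Kenyon cells, compartments ``g1..g5``,
``a1..a3``, ``b1``, ``b2``, ``ap1..ap3``, ``bp1``, ``bp2``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger("mbcs")

SUPER_CLASSES = ("PN", "KC", "MBON", "DAN", "other")
MODALITIES = ("olfactory", "thermo_hygro", "visual", "gustatory", "mixed", "none")
SITE_CLASSES = ("dendrite", "axon", "unknown")

#: the 15 lobe compartments plus calyx regions and the distal pedunculus core
LOBE_COMPARTMENTS = (
    "g1", "g2", "g3", "g4", "g5",
    "a1", "a2", "a3", "b1", "b2",
    "ap1", "ap2", "ap3", "bp1", "bp2",
)
CALYX_REGIONS = ("CA", "dACA", "lACA", "vACA", "pedc")
KNOWN_COMPARTMENTS = frozenset(LOBE_COMPARTMENTS) | frozenset(CALYX_REGIONS)

NEURON_COLUMNS = (
    "neuron_id", "super_class", "cell_type", "subtype", "modality",
    "glomerulus", "compartments_dendrite", "compartments_axon",
)
EDGE_COLUMNS = ("pre_id", "post_id", "weight", "post_site_class")
SYNAPSE_COLUMNS = ("pre_id", "post_id", "x_um", "y_um", "z_um", "region")

_NORMALIZED_KINDS = ("counts", "input_fractions", "binary", "effective", "row_fractions")


# ---------------------------------------------------------------------------
# connectivity matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectivityMatrix:
    """A labelled rectangular matrix of synapse counts or fractions.

    ``normalized`` records the scale of ``values``:

    ``counts``
        raw synapse counts (non-negative).
    ``input_fractions``
        every column is divided by its sum; columns sum to 1 or are
        exactly 0 (an isolated target).
    ``binary``
        0/1 indicator of connections at some synapse threshold.
    ``effective``
        a product of input-fraction matrices (two-step pathways); column
        sums are ≤ 1.
    ``row_fractions``
        rows sum to 1 (e.g. modality fractions per neuron group).
    """

    values: np.ndarray
    row_ids: tuple
    col_ids: tuple
    normalized: str = "counts"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", tuple(self.row_ids))
        object.__setattr__(self, "col_ids", tuple(self.col_ids))
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"({len(self.row_ids)}, {len(self.col_ids)}) ids"
            )
        if self.normalized not in _NORMALIZED_KINDS:
            raise ValueError(f"unknown normalization {self.normalized!r}")
        if np.any(values < 0):
            raise ValueError("connectivity values must be non-negative")
        if self.normalized == "input_fractions":
            sums = values.sum(axis=0)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0))
            if np.any(bad):
                raise ValueError("input_fractions columns must sum to 1 or 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids),
                            columns=list(self.col_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, normalized: str = "counts"
                   ) -> "ConnectivityMatrix":
        return cls(frame.to_numpy(dtype=float), tuple(frame.index),
                   tuple(frame.columns), normalized)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def read_csv(cls, path, normalized: str = "counts") -> "ConnectivityMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls.from_frame(frame, normalized)


def threshold_binarize(m: ConnectivityMatrix, t: int) -> ConnectivityMatrix:
    """Binarise a count matrix at an inclusive synapse threshold.

    An entry is 1 iff the count is ≥ ``t``.  ``t=1`` yields the non-zero
    indicator of ``m``.
    """
    if m.normalized != "counts":
        raise ValueError("threshold_binarize expects a counts matrix")
    if t < 1:
        raise ValueError("threshold must be >= 1")
    return ConnectivityMatrix((m.values >= t).astype(float),
                              m.row_ids, m.col_ids, "binary")


def normalize_inputs(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide each column by its sum so total input per target is 1.

    Zero columns (targets with no input from the row set) are kept as zero
    columns, preserving the matrix shape for downstream products, and are
    reported through the package logger.
    """
    if m.normalized != "counts":
        raise ValueError("normalize_inputs expects a counts matrix")
    sums = m.values.sum(axis=0)
    zero = sums == 0
    if np.any(zero):
        names = [m.col_ids[i] for i in np.flatnonzero(zero)]
        logger.warning("normalize_inputs: %d zero-input columns kept as zeros: %s",
                       len(names), names[:10])
    out = m.values / np.where(zero, 1.0, sums)
    out[:, zero] = 0.0
    return ConnectivityMatrix(out, m.row_ids, m.col_ids, "input_fractions")


def effective_connectivity(a: ConnectivityMatrix, b: ConnectivityMatrix
                           ) -> ConnectivityMatrix:
    """Two-step effective connectivity: the product of input-fraction matrices.

    Entry (i, j) is the sum over intermediates k of ``a[i, k] * b[k, j]`` —
    the fraction of j's input attributable to source i through one hop.
    Column sums are ≤ 1, with equality when all of b's inputs come from a's
    rows.  Longer chains can be formed by repeated application but the
    default analyses use exactly two steps.
    """
    if a.col_ids != b.row_ids:
        raise ValueError("intermediate ids of the two matrices do not match")
    for m in (a, b):
        if m.normalized != "input_fractions":
            raise ValueError("effective_connectivity expects input_fractions matrices")
    return ConnectivityMatrix(a.values @ b.values, a.row_ids, b.col_ids, "effective")


# ---------------------------------------------------------------------------
# connectome container and I/O
# ---------------------------------------------------------------------------

def _parse_compartments(value) -> frozenset:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(value)
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return frozenset()
    return frozenset(part for part in str(value).split(";") if part)


@dataclass
class Connectome:
    """Neurons, weighted synaptic edges, and optional synapse sites.

    ``neurons`` is indexed by ``neuron_id`` with columns ``super_class``,
    ``cell_type``, ``subtype``, ``modality``, ``glomerulus``,
    ``compartments_dendrite`` and ``compartments_axon`` (frozensets).
    ``edges`` has columns ``pre_id``, ``post_id``, ``weight`` (non-negative
    int) and ``post_site_class``.  Every edge endpoint must exist in
    ``neurons``; at most one edge per (pre, post, site-class) triple.
    """

    neurons: pd.DataFrame
    edges: pd.DataFrame
    synapses: pd.DataFrame | None = None

    def __post_init__(self):
        n = self.neurons
        if n.index.name != "neuron_id":
            if "neuron_id" in n.columns:
                n = n.set_index("neuron_id")
            else:
                n = n.rename_axis("neuron_id")
        if n.index.duplicated().any():
            dupes = n.index[n.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate neuron_id: {dupes}")
        for col in ("compartments_dendrite", "compartments_axon"):
            if col not in n.columns:
                n[col] = [frozenset()] * len(n)
            else:
                n[col] = [_parse_compartments(v) for v in n[col]]
        for col in ("super_class", "cell_type", "subtype", "modality", "glomerulus"):
            if col not in n.columns:
                n[col] = None
        self.neurons = n

        e = self.edges.copy()
        for col in ("pre_id", "post_id", "weight"):
            if col not in e.columns:
                raise ValueError(f"edge table missing column {col!r}")
        if "post_site_class" not in e.columns:
            e["post_site_class"] = "unknown"
        e["post_site_class"] = e["post_site_class"].fillna("unknown")
        if (e["weight"] < 0).any():
            raise ValueError("edge weights must be non-negative")
        e["weight"] = e["weight"].astype(np.int64)
        known = set(n.index)
        for col in ("pre_id", "post_id"):
            missing = set(e[col]) - known
            if missing:
                raise ValueError(
                    f"edge {col} references absent neuron(s): {sorted(map(str, missing))}")
        if e.duplicated(["pre_id", "post_id", "post_site_class"]).any():
            raise ValueError("duplicate (pre, post, post_site_class) edges")
        self.edges = e.reset_index(drop=True)

        if self.synapses is not None:
            s = self.synapses.copy()
            for col in ("pre_id", "post_id", "x_um", "y_um", "z_um"):
                if col not in s.columns:
                    raise ValueError(f"synapse table missing column {col!r}")
            if "region" not in s.columns:
                s["region"] = None
            coords = s[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
            if not np.all(np.isfinite(coords)):
                raise ValueError("synapse positions must be finite")
            for col in ("pre_id", "post_id"):
                missing = set(s[col]) - known
                if missing:
                    raise ValueError(
                        f"synapse {col} references absent neuron(s): "
                        f"{sorted(map(str, missing))}")
            pairs = set(zip(e["pre_id"], e["post_id"]))
            orphan = ~s.apply(lambda r: (r["pre_id"], r["post_id"]) in pairs, axis=1)
            if orphan.any():
                logger.warning("%d synapse sites do not match any edge", int(orphan.sum()))
            self.synapses = s.reset_index(drop=True)

    # -- convenience -------------------------------------------------------
    def ids_of(self, super_class: str) -> list:
        mask = self.neurons["super_class"] == super_class
        return list(self.neurons.index[mask])

    def copy(self) -> "Connectome":
        return Connectome(self.neurons.copy(), self.edges.copy(),
                          None if self.synapses is None else self.synapses.copy())


def read_connectome(neuron_table, edge_table, synapse_table=None) -> Connectome:
    """Read a connectome from the CSV dialects.

    ``neuron_table`` columns: neuron_id, super_class, cell_type, subtype,
    modality, glomerulus, compartments_dendrite, compartments_axon (the
    compartment columns are semicolon-separated).  ``edge_table`` columns:
    pre_id, post_id, weight, post_site_class.  ``synapse_table`` columns:
    pre_id, post_id, x_um, y_um, z_um, region.
    """
    neurons = pd.read_csv(neuron_table, dtype={"neuron_id": str})
    if "neuron_id" not in neurons.columns:
        raise ValueError("neuron table missing column 'neuron_id'")
    edges = pd.read_csv(edge_table, dtype={"pre_id": str, "post_id": str})
    synapses = None
    if synapse_table is not None:
        synapses = pd.read_csv(synapse_table, dtype={"pre_id": str, "post_id": str})
    return Connectome(neurons.set_index("neuron_id"), edges, synapses)


def write_connectome(c: Connectome, neuron_table, edge_table,
                     synapse_table=None) -> None:
    """Write a connectome back to the CSV dialects (bit-stable given order)."""
    n = c.neurons.copy()
    for col in ("compartments_dendrite", "compartments_axon"):
        n[col] = [";".join(sorted(v)) for v in n[col]]
    n = n[["super_class", "cell_type", "subtype", "modality", "glomerulus",
           "compartments_dendrite", "compartments_axon"]]
    n.to_csv(neuron_table, index_label="neuron_id")
    c.edges[list(EDGE_COLUMNS)].to_csv(edge_table, index=False)
    if synapse_table is not None and c.synapses is not None:
        c.synapses[list(SYNAPSE_COLUMNS)].to_csv(synapse_table, index=False)


# ---------------------------------------------------------------------------
# selectors and matrices from connectomes
# ---------------------------------------------------------------------------

Selector = "str | Sequence | Mapping | Callable[[pd.DataFrame], pd.Series]"


def select_ids(c: Connectome, selector) -> list:
    """Resolve a neuron selector to an ordered list of neuron ids.

    Accepted forms: an explicit sequence of ids (order preserved); a string
    matching a super_class or, failing that, a cell_type; a mapping of
    neuron-table column to value or set of values; or a callable taking the
    neuron table and returning a boolean mask.
    """
    n = c.neurons
    if isinstance(selector, str):
        if selector in SUPER_CLASSES:
            ids = list(n.index[n["super_class"] == selector])
        else:
            ids = list(n.index[n["cell_type"] == selector])
    elif isinstance(selector, Mapping):
        mask = pd.Series(True, index=n.index)
        for col, val in selector.items():
            if isinstance(val, (set, frozenset, list, tuple)):
                mask &= n[col].isin(list(val))
            else:
                mask &= n[col] == val
        ids = list(n.index[mask])
    elif callable(selector):
        ids = list(n.index[selector(n)])
    else:
        ids = list(selector)
        missing = set(ids) - set(n.index)
        if missing:
            raise ValueError(f"selector references absent neuron(s): "
                             f"{sorted(map(str, missing))}")
    if not ids:
        raise ValueError(f"selector {selector!r} matched no neurons")
    return ids


def to_matrix(c: Connectome, rows, cols, site_class=None) -> ConnectivityMatrix:
    """Total synapse weight between two neuron sets as a counts matrix.

    ``site_class`` optionally restricts edges by postsynaptic site class
    (a string or a collection of the values dendrite/axon/unknown); missing
    pairs are 0.
    """
    row_ids = select_ids(c, rows)
    col_ids = select_ids(c, cols)
    e = c.edges
    if site_class is not None:
        wanted = {site_class} if isinstance(site_class, str) else set(site_class)
        e = e[e["post_site_class"].isin(wanted)]
    e = e[e["pre_id"].isin(row_ids) & e["post_id"].isin(col_ids)]
    values = np.zeros((len(row_ids), len(col_ids)))
    if len(e):
        ri = {k: i for i, k in enumerate(row_ids)}
        ci = {k: i for i, k in enumerate(col_ids)}
        grouped = e.groupby(["pre_id", "post_id"], sort=False)["weight"].sum()
        for (pre, post), w in grouped.items():
            values[ri[pre], ci[post]] += w
    return ConnectivityMatrix(values, row_ids, col_ids, "counts")


# ---------------------------------------------------------------------------
# modality fractions and KC grouping
# ---------------------------------------------------------------------------

SENSORY_MODALITIES = ("olfactory", "thermo_hygro", "visual", "gustatory")

KC_GROUPS = ("olfactory", "olfactory_thermo_hygro", "olfactory_visual")


def _sensory_pn_ids(c: Connectome) -> list:
    n = c.neurons
    mask = (n["super_class"] == "PN") & n["modality"].isin(SENSORY_MODALITIES)
    ids = list(n.index[mask])
    if not ids:
        raise ValueError("no PNs with sensory modality annotations")
    return ids


def modality_input_fractions(c: Connectome, level: str = "kc_type"
                             ) -> ConnectivityMatrix:
    """Fraction of sensory input per modality, by KC, KC type, or MBON.

    For ``level`` in {"kc", "kc_type"} the fractions are computed from direct
    PN→KC synapse counts.  For ``level="mbon"`` the PN→MBON path uses
    two-step effective connectivity (PN→KC and KC→MBON input fractions
    multiplied), and each MBON's modality totals are divided by the total
    sensory input to that MBON.  Rows are groups, columns are modalities;
    rows sum to 1 whenever the group has any sensory input.
    """
    pn_ids = _sensory_pn_ids(c)
    pn_modality = c.neurons.loc[pn_ids, "modality"].to_numpy()
    kc_ids = c.ids_of("KC")
    counts = to_matrix(c, pn_ids, kc_ids)

    def _by_modality(values: np.ndarray) -> np.ndarray:
        # collapse PN rows onto the fixed modality order
        out = np.zeros((len(SENSORY_MODALITIES), values.shape[1]))
        for i, mod in enumerate(SENSORY_MODALITIES):
            out[i] = values[pn_modality == mod].sum(axis=0)
        return out

    if level in ("kc", "kc_type"):
        per_kc = _by_modality(counts.values)  # modalities x KCs
        if level == "kc_type":
            types = c.neurons.loc[kc_ids, "cell_type"]
            uniq = list(dict.fromkeys(types))
            agg = np.zeros((len(SENSORY_MODALITIES), len(uniq)))
            for j, t in enumerate(uniq):
                agg[:, j] = per_kc[:, (types == t).to_numpy()].sum(axis=1)
            per_kc, group_ids = agg, uniq
        else:
            group_ids = kc_ids
    elif level == "mbon":
        mbon_ids = c.ids_of("MBON")
        a = normalize_inputs(counts)
        b = normalize_inputs(to_matrix(c, kc_ids, mbon_ids))
        eff = effective_connectivity(a, b)
        per_kc = _by_modality(eff.values)
        group_ids = mbon_ids
    else:
        raise ValueError(f"unknown level {level!r}")

    totals = per_kc.sum(axis=0)
    zero = totals == 0
    if np.any(zero):
        logger.warning("modality_input_fractions: %d groups with no sensory input",
                       int(zero.sum()))
    frac = per_kc / np.where(zero, 1.0, totals)
    frac[:, zero] = 0.0
    return ConnectivityMatrix(frac.T, group_ids, SENSORY_MODALITIES, "row_fractions")


def group_kcs_by_modality(fractions: ConnectivityMatrix,
                          threshold: float = 0.25) -> dict:
    """Assign each KC to a modality stream from its sensory input fractions.

    A KC is ``olfactory_thermo_hygro`` or ``olfactory_visual`` when its
    dominant non-olfactory fraction meets the threshold (default 0.25),
    otherwise ``olfactory``.  Deterministic; thermo wins ties.
    """
    cols = {m: i for i, m in enumerate(fractions.col_ids)}
    out = {}
    for i, kc in enumerate(fractions.row_ids):
        th = fractions.values[i, cols["thermo_hygro"]]
        vi = fractions.values[i, cols["visual"]]
        if max(th, vi) >= threshold:
            out[kc] = "olfactory_thermo_hygro" if th >= vi else "olfactory_visual"
        else:
            out[kc] = "olfactory"
    return out


# ---------------------------------------------------------------------------
# MBON -> DAN feedback motifs
# ---------------------------------------------------------------------------

def classify_dan_feedback(c: Connectome, threshold: int = 5,
                          dendrite_only: bool = True) -> dict:
    """Classify each DAN's MBON feedback as self / cross / both / neither.

    A feeding MBON is "same-compartment" when its dendritic compartments
    intersect the DAN's axonal compartments.  A DAN is ``self`` when all its
    above-threshold MBON inputs are same-compartment, ``cross`` when none
    are, ``both`` for a mixture and ``neither`` with no MBON input.  When
    ``dendrite_only`` is set, axon-class synapses onto the DAN are excluded;
    edges without a site-class annotation are treated as dendritic.
    """
    n = c.neurons
    mbon_ids = set(c.ids_of("MBON"))
    dan_ids = c.ids_of("DAN")
    e = c.edges
    e = e[e["pre_id"].isin(mbon_ids) & e["post_id"].isin(dan_ids)]
    if dendrite_only:
        e = e[e["post_site_class"] != "axon"]
    weight = e.groupby(["post_id", "pre_id"])["weight"].sum()

    out = {}
    for dan in dan_ids:
        comp_ax = n.at[dan, "compartments_axon"]
        if not comp_ax:
            raise ValueError(f"DAN {dan!r} lacks axonal compartment annotation")
        feeders = weight.loc[dan] if dan in weight.index.get_level_values(0) else None
        self_found = cross_found = False
        if feeders is not None:
            for mbon, w in feeders.items():
                if w < threshold:
                    continue
                if n.at[mbon, "compartments_dendrite"] & comp_ax:
                    self_found = True
                else:
                    cross_found = True
        out[dan] = ("both" if self_found and cross_found
                    else "self" if self_found
                    else "cross" if cross_found
                    else "neither")
    return out


# ---------------------------------------------------------------------------
# skeletons and root-distance ECDFs
# ---------------------------------------------------------------------------

_SWC_CLASS = {1: "soma", 2: "axon", 3: "dendrite"}


@dataclass
class Skeleton:
    """A rooted neuronal tree with 3D node positions in micrometres."""

    nodes: pd.DataFrame  # index node_id; columns x, y, z, parent, node_class
    root: int = field(init=False)

    def __post_init__(self):
        n = self.nodes
        roots = n.index[n["parent"] == -1]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if "node_class" not in n.columns:
            n["node_class"] = None
        # verify the parent map is acyclic and connected by walking to root
        reach = {self.root}
        for nid in n.index:
            trail = []
            cur = nid
            while cur not in reach:
                trail.append(cur)
                cur = int(n.at[cur, "parent"])
                if cur == -1 or cur in trail:
                    raise ValueError("parent map is not a connected rooted tree")
                if cur not in n.index:
                    raise ValueError(f"parent {cur} of node {trail[-1]} missing")
            reach.update(trail)

    @classmethod
    def from_swc(cls, path) -> "Skeleton":
        # SWC: id, structure type, x, y, z, radius, parent (1-based ids, root -1)
        cols = ["node_id", "swc_type", "x", "y", "z", "radius", "parent"]
        table = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=cols)
        nodes = table.set_index("node_id")[["x", "y", "z", "parent"]]
        nodes["node_class"] = table.set_index("node_id")["swc_type"].map(
            _SWC_CLASS).fillna("other")
        return cls(nodes)

    def to_swc(self, path) -> None:
        n = self.nodes
        inv = {v: k for k, v in _SWC_CLASS.items()}
        with open(path, "w") as fh:
            for nid, row in n.iterrows():
                swc_type = inv.get(row.get("node_class"), 0)
                fh.write(f"{nid} {swc_type} {row.x:.6g} {row.y:.6g} {row.z:.6g} "
                         f"1.0 {int(row.parent)}\n")

    def root_distances(self) -> pd.Series:
        """Geodesic along-tree distance from the root, per node."""
        n = self.nodes
        xyz = n[["x", "y", "z"]].to_numpy(dtype=float)
        pos = {nid: xyz[i] for i, nid in enumerate(n.index)}
        dist: dict = {self.root: 0.0}
        for nid in n.index:
            stack = []
            cur = nid
            while cur not in dist:
                stack.append(cur)
                cur = int(n.at[cur, "parent"])
            base = dist[cur]
            for node in reversed(stack):
                parent = int(n.at[node, "parent"])
                base = dist[parent] + float(np.linalg.norm(pos[node] - pos[parent]))
                dist[node] = base
        return pd.Series(dist).reindex(n.index)


@dataclass(frozen=True)
class Ecdf:
    """Empirical CDF over [0, 1]-normalised distances."""

    values: np.ndarray  # sorted

    def __call__(self, x) -> np.ndarray:
        return np.searchsorted(self.values, np.asarray(x), side="right") / len(self.values)

    @property
    def median(self) -> float:
        return float(np.median(self.values))


def root_distance_ecdf(skeleton: Skeleton, synapses, reference,
                       dendrite_only: bool = True):
    """ECDFs of synapse distance from the dendritic root, normalised to [0, 1].

    Synapse positions (arrays of xyz, µm) are snapped to the nearest skeleton
    node; the geodesic root distance of that node is divided by the maximum
    root distance over dendrite-class nodes (all nodes when the skeleton
    carries no class labels).  Returns ``(query_ecdf, reference_ecdf,
    reference_half_distance)`` where the half distance is the normalised
    distance at which half of the reference (KC) synapses have occurred.
    """
    synapses = np.atleast_2d(np.asarray(synapses, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if synapses.size == 0 or reference.size == 0:
        raise ValueError("empty synapse set")
    if len(skeleton.nodes) < 2:
        raise ValueError("skeleton must have more than one node")

    dist = skeleton.root_distances()
    classes = skeleton.nodes["node_class"]
    if dendrite_only and (classes == "dendrite").any():
        denom = float(dist[classes == "dendrite"].max())
    else:
        denom = float(dist.max())
    if denom == 0:
        raise ValueError("degenerate skeleton: zero maximal root distance")

    tree = cKDTree(skeleton.nodes[["x", "y", "z"]].to_numpy(dtype=float))
    node_ids = np.asarray(skeleton.nodes.index)

    def _norm_dists(points):
        _, idx = tree.query(points)
        return np.sort(dist.loc[node_ids[idx]].to_numpy() / denom)

    q = Ecdf(_norm_dists(synapses))
    r = Ecdf(_norm_dists(reference))
    return q, r, r.median
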