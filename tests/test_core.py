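import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mbcs import (ConnectivityMatrix, Skeleton, classify_dan_feedback,
                  effective_connectivity, group_kcs_by_modality,
                  modality_input_fractions, normalize_inputs, read_connectome,
                  root_distance_ecdf, threshold_binarize, to_matrix,
                  write_connectome)
from mbcs.core import Connectome


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_read_write_round_trip(toy_connectome, tmp_path):
    n1, e1, s1 = tmp_path / "n.csv", tmp_path / "e.csv", tmp_path / "s.csv"
    write_connectome(toy_connectome, n1, e1)
    back = read_connectome(n1, e1)
    assert len(back.neurons) == 9 and len(back.edges) == 11
    # writing again is byte-stable
    n2, e2 = tmp_path / "n2.csv", tmp_path / "e2.csv"
    write_connectome(back, n2, e2)
    assert n1.read_bytes() == n2.read_bytes()
    assert e1.read_bytes() == e2.read_bytes()
    for col in ("super_class", "cell_type", "compartments_dendrite",
                "compartments_axon"):
        assert list(back.neurons[col]) == list(toy_connectome.neurons[col])
    pd.testing.assert_frame_equal(back.edges, toy_connectome.edges)


def test_edge_referencing_absent_neuron_is_named(tmp_path):
    pd.DataFrame({"neuron_id": ["A"], "super_class": ["KC"]}).to_csv(
        tmp_path / "n.csv", index=False)
    pd.DataFrame({"pre_id": ["A"], "post_id": ["X"], "weight": [3]}).to_csv(
        tmp_path / "e.csv", index=False)
    with pytest.raises(ValueError, match="X"):
        read_connectome(tmp_path / "n.csv", tmp_path / "e.csv")


def test_duplicate_neuron_id_rejected():
    neurons = pd.DataFrame({"neuron_id": ["A", "A"], "super_class": ["KC", "KC"]})
    with pytest.raises(ValueError, match="duplicate"):
        Connectome(neurons.set_index("neuron_id"), pd.DataFrame(
            {"pre_id": [], "post_id": [], "weight": []}))


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def test_to_matrix_totals_and_site_class_filter(toy_connectome):
    m = to_matrix(toy_connectome, ["P1"], ["K1", "K2"])
    assert m.values.tolist() == [[6.0, 1.0]]
    # dendrite filter drops the 3-synapse axo-axonal component of M1->D1
    dend = to_matrix(toy_connectome, ["M1"], ["D1"], site_class="dendrite")
    both = to_matrix(toy_connectome, ["M1"], ["D1"])
    assert dend.values[0, 0] == 7.0 and both.values[0, 0] == 10.0
    axo = to_matrix(toy_connectome, ["M2"], ["D1"], site_class="axon")
    assert axo.values[0, 0] == 0.0


def test_to_matrix_matches_brute_force_edge_scan(default_result):
    c = default_result.connectome
    kcs = c.ids_of("KC")[:40]
    m = to_matrix(c, kcs, kcs)
    expected = np.zeros_like(m.values)
    idx = {k: i for i, k in enumerate(kcs)}
    for _, row in c.edges.iterrows():
        if row.pre_id in idx and row.post_id in idx:
            expected[idx[row.pre_id], idx[row.post_id]] += row.weight
    assert np.array_equal(m.values, expected)
    assert np.all(np.diag(m.values) == 0)  # no autapses emitted


def test_threshold_binarize_examples():
    m = ConnectivityMatrix([[6, 4], [5, 0]], ["a", "b"], ["x", "y"])
    assert threshold_binarize(m, 5).values.tolist() == [[1.0, 0.0], [1.0, 0.0]]
    zeros = ConnectivityMatrix(np.zeros((2, 2)), ["a", "b"], ["x", "y"])
    assert not threshold_binarize(zeros, 3).values.any()
    assert np.array_equal(threshold_binarize(m, 1).values, (m.values > 0))
    with pytest.raises(ValueError):
        threshold_binarize(m, 0)


@given(st.integers(1, 12), st.integers(0, 2**32 - 1))
def test_threshold_support_monotone_in_t(t, seed):
    values = np.random.default_rng(seed).integers(0, 10, size=(4, 5))
    m = ConnectivityMatrix(values, list("abcd"), list("vwxyz"))
    lo = threshold_binarize(m, t).values
    hi = threshold_binarize(m, t + 1).values
    assert np.all(hi <= lo)


def test_normalize_inputs_columns_and_zero_column(caplog):
    m = ConnectivityMatrix([[2, 0], [2, 0]], ["a", "b"], ["x", "y"])
    with caplog.at_level("WARNING", logger="mbcs"):
        f = normalize_inputs(m)
    assert f.values[:, 0].tolist() == [0.5, 0.5]
    assert not f.values[:, 1].any()
    assert "zero-input" in caplog.text
    rng = np.random.default_rng(0)
    m = ConnectivityMatrix(rng.integers(1, 9, (5, 4)), range(5), range(4))
    sums = normalize_inputs(m).values.sum(axis=0)
    assert np.all(np.abs(sums - 1) < 1e-12)


@given(st.integers(0, 2**32 - 1))
def test_effective_connectivity_equals_path_sum_oracle(seed):
    rng = np.random.default_rng(seed)
    a = normalize_inputs(ConnectivityMatrix(rng.integers(0, 7, (5, 4)) + 0.0,
                                            list("ABCDE"), list("wxyz")))
    b = normalize_inputs(ConnectivityMatrix(rng.integers(0, 7, (4, 3)) + 0.0,
                                            list("wxyz"), list("123")))
    eff = effective_connectivity(a, b)
    for i in range(5):
        for j in range(3):
            path_sum = sum(a.values[i, k] * b.values[k, j] for k in range(4))
            assert eff.values[i, j] == pytest.approx(path_sum, abs=1e-12)
    assert np.all(eff.values.sum(axis=0) <= 1 + 1e-9)


def test_effective_connectivity_trivial_chains():
    a = ConnectivityMatrix([[1.0]], ["PN1"], ["KC1"], "input_fractions")
    b = ConnectivityMatrix([[1.0]], ["KC1"], ["MBON1"], "input_fractions")
    assert effective_connectivity(a, b).values[0, 0] == 1.0
    a2 = ConnectivityMatrix([[0.5], [0.5]], ["PN1", "PN2"], ["KC1"],
                            "input_fractions")
    eff = effective_connectivity(a2, b)
    assert eff.values.ravel().tolist() == [0.5, 0.5]
    with pytest.raises(ValueError, match="ids"):
        effective_connectivity(a2, ConnectivityMatrix([[1.0]], ["other"],
                                                      ["MBON1"], "input_fractions"))


# ---------------------------------------------------------------------------
# modality fractions and grouping
# ---------------------------------------------------------------------------

def test_modality_fraction_examples(toy_connectome):
    fr = modality_input_fractions(toy_connectome, level="kc").to_frame()
    # K2: 1 olfactory + 9 visual synapses
    assert fr.loc["K2", "visual"] == pytest.approx(0.9)
    # K1: 6 olfactory + 2 thermo -> (0.75, 0.25)
    assert fr.loc["K1", "olfactory"] == pytest.approx(0.75)
    assert fr.loc["K1", "thermo_hygro"] == pytest.approx(0.25)
    by_type = modality_input_fractions(toy_connectome, level="kc_type").to_frame()
    assert by_type.loc["KCgd", "visual"] == pytest.approx(0.9)


def test_group_kcs_by_modality_threshold_rule():
    fr = ConnectivityMatrix(
        [[1.0, 0.0, 0.0, 0.0],
         [0.5, 0.5, 0.0, 0.0],
         [0.6, 0.1, 0.3, 0.0]],
        ["K1", "K2", "K3"],
        ("olfactory", "thermo_hygro", "visual", "gustatory"), "row_fractions")
    groups = group_kcs_by_modality(fr, threshold=0.25)
    assert groups == {"K1": "olfactory", "K2": "olfactory_thermo_hygro",
                      "K3": "olfactory_visual"}


def test_mbon_level_fractions_use_effective_connectivity(toy_connectome):
    fr = modality_input_fractions(toy_connectome, level="mbon").to_frame()
    # M2's only KC input is K1, whose sensory input is 3/4 olfactory 1/4 thermo
    assert fr.loc["M2", "olfactory"] == pytest.approx(0.75)
    assert fr.loc["M2", "thermo_hygro"] == pytest.approx(0.25)
    assert fr.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])


# ---------------------------------------------------------------------------
# DAN feedback motifs
# ---------------------------------------------------------------------------

def test_classify_dan_feedback_motifs(toy_connectome):
    out = classify_dan_feedback(toy_connectome, threshold=5)
    assert out["D1"] == "self"       # only M1 (g1 dendrite) feeds D1 (g1 axon)
    assert out["D2"] == "both"       # M1 is cross, M2 is self for a3
    # raising the threshold above both inputs makes D2 'neither'
    assert classify_dan_feedback(toy_connectome, threshold=12)["D2"] == "neither"


def test_classify_dan_feedback_invariant_to_order_and_relabels(toy_connectome):
    base = classify_dan_feedback(toy_connectome, threshold=5)
    shuffled = Connectome(toy_connectome.neurons.copy(),
                          toy_connectome.edges.iloc[::-1].reset_index(drop=True))
    assert classify_dan_feedback(shuffled, threshold=5) == base
    mapping = {i: f"n_{i}" for i in toy_connectome.neurons.index}
    renamed_neurons = toy_connectome.neurons.rename(index=mapping)
    renamed_edges = toy_connectome.edges.assign(
        pre_id=toy_connectome.edges["pre_id"].map(mapping),
        post_id=toy_connectome.edges["post_id"].map(mapping))
    renamed = classify_dan_feedback(Connectome(renamed_neurons, renamed_edges),
                                    threshold=5)
    assert renamed == {mapping[k]: v for k, v in base.items()}


def test_unannotated_dan_is_an_error(toy_connectome):
    c = toy_connectome.copy()
    c.neurons.at["D1", "compartments_axon"] = frozenset()
    with pytest.raises(ValueError, match="D1"):
        classify_dan_feedback(c)


# ---------------------------------------------------------------------------
# skeletons and root-distance ECDFs
# ---------------------------------------------------------------------------

def _path_skeleton(n=5, step=2.0):
    nodes = pd.DataFrame({
        "x": np.arange(n) * step, "y": 0.0, "z": 0.0,
        "parent": [-1] + list(range(1, n)),
        "node_class": "dendrite",
    }, index=pd.Index(range(1, n + 1), name="node_id"))
    return Skeleton(nodes)


def test_root_distance_ecdf_limits():
    skel = _path_skeleton()
    root = np.zeros((3, 3))
    q, _, _ = root_distance_ecdf(skel, root, root)
    assert q(0.0) == 1.0
    tip = np.array([[8.0, 0, 0]])
    q, r, half = root_distance_ecdf(skel, tip, root)
    assert q.values.tolist() == [1.0]
    assert half == 0.0


def test_root_distance_ecdf_matches_tree_path_oracle():
    import networkx as nx
    rng = np.random.default_rng(4)
    # random binary-ish tree with 12 nodes
    parents = [-1] + [int(rng.integers(1, i + 1)) for i in range(1, 12)]
    xyz = rng.normal(0, 10, (12, 3))
    nodes = pd.DataFrame({"x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
                          "parent": parents, "node_class": "dendrite"},
                         index=pd.Index(range(1, 13), name="node_id"))
    skel = Skeleton(nodes)
    g = nx.Graph()
    for nid in range(2, 13):
        p = parents[nid - 1]
        g.add_edge(nid, p, weight=float(np.linalg.norm(xyz[nid - 1] - xyz[p - 1])))
    oracle = nx.single_source_dijkstra_path_length(g, 1)
    dist = skel.root_distances()
    for nid in range(1, 13):
        assert dist[nid] == pytest.approx(oracle.get(nid, 0.0), abs=1e-9)
    # synapses exactly on nodes: ECDF equals sorted normalized oracle dists
    pts = xyz[[2, 5, 9]]
    q, _, _ = root_distance_ecdf(skel, pts, xyz)
    expected = np.sort([oracle[i + 1] for i in (2, 5, 9)]) / max(oracle.values())
    assert np.allclose(q.values, expected)


def test_root_distance_ecdf_rigid_motion_invariance():
    skel = _path_skeleton(6)
    pts = np.array([[2.0, 0, 0], [6.0, 0, 0]])
    q1, r1, h1 = root_distance_ecdf(skel, pts, pts)
    # rotate 90 deg about z and translate
    rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
    shift = np.array([5.0, -3.0, 2.0])
    nodes = skel.nodes.copy()
    nodes[["x", "y", "z"]] = nodes[["x", "y", "z"]].to_numpy() @ rot.T + shift
    q2, r2, h2 = root_distance_ecdf(Skeleton(nodes), pts @ rot.T + shift,
                                    pts @ rot.T + shift)
    assert np.allclose(q1.values, q2.values) and h1 == h2


def test_swc_round_trip(tmp_path):
    skel = _path_skeleton(4)
    path = tmp_path / "tree.swc"
    skel.to_swc(path)
    back = Skeleton.from_swc(path)
    assert back.root == 1
    assert np.allclose(back.nodes[["x", "y", "z"]], skel.nodes[["x", "y", "z"]])
    assert list(back.nodes["node_class"]) == ["dendrite"] * 4
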