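"""MI estimation, DPI pruning, bootstrap consensus reconstruction,
rewiring scores and iTreg-subnetwork selection."""

import numpy as np
import pandas as pd
import pytest

from tregomics import SimConfig, generate_counts, modlog
from tregomics.datamodel import AbundanceMatrix
from tregomics.network import (
    MINetwork,
    apply_dpi,
    mutual_information,
    reconstruct_network,
    rewiring_scores,
    select_hubs,
    select_subnetwork,
    union_networks,
)


# --------------------------------------------------------------------------
# hub selection
# --------------------------------------------------------------------------


def test_select_hubs_triple_intersection_oracle(rng):
    genes = [f"g{i}" for i in range(20)]
    g_scores = pd.DataFrame(
        rng.integers(0, 4, size=(20, 3)), index=genes,
        columns=["time", "G03", "G05"],
    )
    p_scores = pd.DataFrame(
        rng.integers(0, 2, size=(20, 3)), index=genes,
        columns=["time", "G03", "G05"],
    )
    tf = pd.Series(rng.random(20) < 0.5, index=genes)
    hubs = set(select_hubs(g_scores, p_scores, tf))
    expected = {
        g for g in genes
        if (g_scores.loc[g] >= 2).any() and (p_scores.loc[g] >= 1).any() and tf[g]
    }
    assert hubs == expected


def test_select_hubs_requires_all_three_conditions():
    genes = ["deg_dep_notf", "deg_only_tf"]
    g = pd.DataFrame({"time": [3, 3], "G03": [0, 0], "G05": [0, 0]}, index=genes)
    p = pd.DataFrame({"time": [1, 0], "G03": [0, 0], "G05": [0, 0]}, index=genes)
    tf = pd.Series({"deg_dep_notf": False, "deg_only_tf": True})
    assert len(select_hubs(g, p, tf)) == 0


# --------------------------------------------------------------------------
# mutual information
# --------------------------------------------------------------------------


def test_mi_perfect_dependence_fixed_sequence():
    x = np.sin(np.arange(33) * 1.7) * 3 + np.arange(33) * 0.1
    mi, p = mutual_information(x, x)
    # maximal MI for the binning = entropy of the equal-frequency marginal
    # (bins of 6,6,6,5,5,5 at n=33, b=6)
    sizes = np.array([6, 6, 6, 5, 5, 5]) / 33
    h_max = -(sizes * np.log(sizes)).sum()
    assert mi == pytest.approx(h_max, rel=1e-9)
    assert p < 1e-10


def test_mi_symmetry_and_rank_invariance(rng):
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    mi_xy, p_xy = mutual_information(x, y)
    mi_yx, p_yx = mutual_information(y, x)
    assert mi_xy == mi_yx and p_xy == p_yx
    # strictly monotone transforms leave the rank-based estimate unchanged
    mi_t, p_t = mutual_information(np.exp(x), y**3 + 5 * y)
    assert mi_t == pytest.approx(mi_xy)
    assert p_t == pytest.approx(p_xy)


def test_mi_constant_vector():
    x = np.ones(20)
    y = np.arange(20, dtype=float)
    assert mutual_information(x, y) == (0.0, 1.0)


def test_mi_nonnegative_and_input_validation(rng):
    for _ in range(20):
        mi, _ = mutual_information(rng.normal(size=16), rng.normal(size=16))
        assert mi >= 0
    with pytest.raises(ValueError):
        mutual_information(np.arange(5.0), np.arange(5.0))


def test_mi_pvalue_calibration_williams():
    """With the small-sample correction and a sample size adequate for
    the chi-square asymptotics, independent inputs reject at close to the
    nominal 5% level (the plain G statistic is liberal when n ~ b^2)."""
    local = np.random.default_rng(4)
    hits = 0
    n_rep = 2000
    for _ in range(n_rep):
        x = local.random(144)
        y = local.random(144)
        _, p = mutual_information(x, y, williams=True)
        hits += p < 0.05
    assert 0.03 < hits / n_rep < 0.08


# --------------------------------------------------------------------------
# DPI
# --------------------------------------------------------------------------


def _mi_of(x, y):
    return mutual_information(x, y)[0]


def test_dpi_removes_indirect_markov_edge(rng):
    """X -> Y -> Z chain: the X-Z edge is the weakest of the triangle and
    is pruned; the direct edges survive."""
    n = 4000
    x = rng.normal(size=n)
    y = x + rng.normal(0, 0.5, size=n)
    z = y + rng.normal(0, 0.5, size=n)
    edges = {
        ("X", "Y"): _mi_of(x, y),
        ("Y", "Z"): _mi_of(y, z),
        ("X", "Z"): _mi_of(x, z),
    }
    pruned = apply_dpi(edges, hubs={"Y"}, tol=0.1)
    assert set(pruned) == {("X", "Y"), ("Y", "Z")}


def test_dpi_equal_triangle_untouched():
    edges = {("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 1.0}
    assert apply_dpi(edges, hubs={"a"}, tol=0.1) == edges


def test_dpi_tol_one_removes_nothing():
    edges = {("a", "b"): 1.0, ("b", "c"): 0.9, ("a", "c"): 0.01}
    assert apply_dpi(edges, hubs={"a", "b", "c"}, tol=1.0) == edges


def test_dpi_requires_hub_in_triplet():
    edges = {("a", "b"): 1.0, ("b", "c"): 0.9, ("a", "c"): 0.01}
    assert apply_dpi(edges, hubs=set(), tol=0.1) == edges
    assert ("a", "c") not in apply_dpi(edges, hubs={"b"}, tol=0.1)


def test_dpi_idempotent(rng):
    nodes = [f"n{i}" for i in range(8)]
    edges = {}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if rng.random() < 0.5:
                edges[(a, b)] = float(rng.random())
    once = apply_dpi(edges, hubs=set(nodes), tol=0.1)
    twice = apply_dpi(once, hubs=set(nodes), tol=0.1)
    assert once == twice


# --------------------------------------------------------------------------
# reconstruction
# --------------------------------------------------------------------------


def _network_config(seed, **kw):
    base = dict(
        n_genes=120,
        seed=seed,
        n_hubs=2,
        targets_per_hub=10,
        frac_time_de=0.0,
        frac_itreg_de={g: 0.0 for g in ("G03", "G04", "G05", "G06")},
        frac_shared_core=0.0,
        rewired_hub_frac=0.0,
        hub_signal_sd=3.0,
        nb_dispersion=0.01,
        effect_size_log2=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="module")
def reconstructed():
    cfg = _network_config(17)
    counts, design, truth = generate_counts(cfg)
    ml = modlog(counts)
    hubs = truth.genes.index[truth.genes["is_hub"]]
    net = reconstruct_network(ml, hubs, design, window="full",
                              n_bootstraps=100, seed=2)
    return truth, ml, design, hubs, net


def test_reconstruction_recovers_planted_edges(reconstructed):
    truth, _, _, _, net = reconstructed
    true_edges = {
        tuple(sorted((r["hub"], r["target"])))
        for _, r in truth.hub_edges.iterrows()
    }
    found = net.edge_set()
    tp = len(found & true_edges)
    assert tp / max(len(found), 1) >= 0.9
    assert tp / len(true_edges) >= 0.8


def test_reconstruction_deterministic(reconstructed):
    truth, ml, design, hubs, net = reconstructed
    net2 = reconstruct_network(ml, hubs, design, window="full",
                               n_bootstraps=100, seed=2)
    assert net.edge_set() == net2.edge_set()
    pd.testing.assert_frame_equal(net.edges, net2.edges)


def test_reconstruction_every_edge_touches_hub(reconstructed):
    truth, _, _, hubs, net = reconstructed
    hub_set = set(hubs)
    for _, row in net.edges.iterrows():
        assert row["node_a"] in hub_set or row["node_b"] in hub_set
    assert (net.edges["support"] <= net.n_bootstraps).all()
    assert (net.edges["weight"] >= 0).all()


def test_reconstruction_window_too_small(rng):
    from tregomics import SampleDesign

    rows = [
        {"sample_id": f"D{d}_G02_T04", "donor": f"D{d}", "group": "G02",
         "time": "T04"}
        for d in range(3)
    ]
    design = SampleDesign(pd.DataFrame(rows).set_index("sample_id"))
    mat = AbundanceMatrix(
        pd.DataFrame(rng.normal(size=(10, 3)),
                     index=[f"g{i}" for i in range(10)],
                     columns=design.sample_ids)
    )
    with pytest.raises(ValueError, match="< 8"):
        reconstruct_network(mat, ["g0"], design, window="late")


# --------------------------------------------------------------------------
# rewiring
# --------------------------------------------------------------------------


def _net(edges, hubs=()):
    df = pd.DataFrame(
        [{"node_a": a, "node_b": b, "weight": w, "support": 1}
         for (a, b), w in edges.items()],
        columns=["node_a", "node_b", "weight", "support"],
    )
    nodes = pd.Index(sorted({n for e in edges for n in e} | set(hubs)))
    return MINetwork(edges=df, hubs=pd.Index(sorted(hubs)), nodes=nodes)


def test_rewiring_identical_incidence_is_zero():
    n1 = _net({("h", "a"): 0.5, ("h", "b"): 0.7}, hubs=["h"])
    n2 = _net({("h", "a"): 1.0, ("h", "b"): 1.4}, hubs=["h"])  # same shape
    dn = rewiring_scores(n1, n2)
    assert dn["h"] == pytest.approx(0.0)  # unit-sum normalization


def test_rewiring_single_network_node_bounded():
    n1 = _net({("h", "a"): 0.5, ("h", "b"): 0.5}, hubs=["h"])
    n2 = _net({("x", "y"): 1.0})
    dn = rewiring_scores(n1, n2)
    assert dn["h"] == pytest.approx(0.5 * (0.5**2 + 0.5**2))
    assert dn["h"] <= 0.5
    assert dn["x"] == pytest.approx(0.5)


def test_rewiring_symmetric():
    n1 = _net({("h", "a"): 0.5, ("h", "b"): 0.3}, hubs=["h"])
    n2 = _net({("h", "a"): 0.2, ("h", "c"): 0.9}, hubs=["h"])
    d12 = rewiring_scores(n1, n2)
    d21 = rewiring_scores(n2, n1)
    pd.testing.assert_series_equal(d12.sort_index(), d21.sort_index())


def test_regime_switch_hub_tops_rewiring():
    """A hub whose single dominant target switches between the early and
    late windows reaches the maximal score and the top 5%."""
    cfg = _network_config(
        101, n_genes=200, n_hubs=10, targets_per_hub=2, rewired_hub_frac=0.1,
        hub_signal_sd=4.0, nb_dispersion=0.005,
    )
    counts, design, truth = generate_counts(cfg)
    ml = modlog(counts)
    hubs = truth.genes.index[truth.genes["is_hub"]]
    early = reconstruct_network(ml, hubs, design, window="early",
                                n_bootstraps=100, seed=1)
    late = reconstruct_network(ml, hubs, design, window="late",
                               n_bootstraps=100, seed=1)
    dn = rewiring_scores(early, late)
    switch = sorted(set(truth.hub_edges.loc[truth.hub_edges["regime"] != "stable",
                                            "hub"]))[0]
    assert dn[switch] >= np.quantile(dn.to_numpy(), 0.95)


# --------------------------------------------------------------------------
# subnetwork selection
# --------------------------------------------------------------------------


def test_select_subnetwork_brute_force(rng):
    genes = [f"g{i}" for i in range(30)]
    deg = pd.DataFrame(
        rng.integers(0, 4, size=(30, 4)), index=genes,
        columns=["G03", "G04", "G05", "G06"],
    )
    edges = {}
    for i in range(0, 28, 2):
        edges[(genes[i], genes[i + 1])] = float(rng.random())
    net = _net(edges, hubs=[genes[0]])
    sub = select_subnetwork(net, deg, anchor="g0")
    expected_nodes = {g for g in genes if (deg.loc[g] >= 2).all()} | {"g0"}
    assert set(sub.nodes) <= expected_nodes
    for _, row in sub.edges.iterrows():
        assert row["node_a"] in expected_nodes
        assert row["node_b"] in expected_nodes
    # gene DEG in only 3 of 4 groups is excluded
    three_of_four = deg.index[((deg >= 2).sum(axis=1) == 3)]
    for g in three_of_four:
        if g != "g0":
            assert g not in set(sub.nodes)


def test_select_subnetwork_anchor_always_included():
    deg = pd.DataFrame(
        {"G03": [0], "G04": [0], "G05": [0], "G06": [0]}, index=["FOXP3"]
    )
    net = _net({("FOXP3", "x"): 1.0}, hubs=["FOXP3"])
    sub = select_subnetwork(net, deg, anchor="FOXP3")
    assert "FOXP3" in set(sub.nodes)


def test_union_networks_keeps_max_weight():
    n1 = _net({("h", "a"): 0.5}, hubs=["h"])
    n2 = _net({("h", "a"): 0.8, ("h", "b"): 0.2}, hubs=["h"])
    u = union_networks(n1, n2)
    w = dict(zip(zip(u.edges["node_a"], u.edges["node_b"]), u.edges["weight"]))
    assert w[("a", "h")] == 0.8 or w[("h", "a")] == 0.8
    assert len(u.edges) == 2
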