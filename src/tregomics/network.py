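"""Hub-centered mutual-information network reconstruction.

Hubs are transcription factors differentially expressed at both the RNA
and protein level.  Edges between a hub and every other expressed gene
are scored by a rank-based, equal-frequency-binned mutual-information
estimator ("binning MI") with a chi-square (G-test) p-value; bootstrap
networks are pruned by the data processing inequality (DPI) and combined
into a consensus by a binomial support test.  Early (0-6 h) and late
(24 h-6 d) networks are compared through a per-node rewiring score

    D_n = 1/2 * || w_early - w_late ||^2

on unit-sum normalized incident-edge weight vectors ("Dn-like").
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import AbundanceMatrix, SampleDesign

log = logging.getLogger(__name__)

#: sample windows used to reconstruct the two network states
WINDOWS: dict[str, dict] = {
    "early": {"times": ("T01", "T02", "T03"), "groups": ("G01", "G02", "G03", "G04", "G05", "G06")},
    "late": {"times": ("T04", "T05", "T06"), "groups": ("G02", "G03", "G04", "G05", "G06")},
    "full": {"times": None, "groups": None},
}


# --------------------------------------------------------------------------
# hub selection
# --------------------------------------------------------------------------


def select_hubs(
    g_scores: pd.DataFrame,
    p_scores: pd.DataFrame,
    tf_flags: pd.Series,
    rna_contrasts: tuple[str, ...] = ("time", "G03", "G05"),
    protein_contrasts: tuple[str, ...] = ("time", "G03", "G05"),
) -> pd.Index:
    """Transcription factors that are DEGs and DEPs.

    A gene qualifies when any of its RNA G scores over the given
    contrasts is >= 2, any of its protein P scores is 1, and it is
    annotated as a TF.
    """
    rna_cols = [c for c in rna_contrasts if c in g_scores.columns]
    prot_cols = [c for c in protein_contrasts if c in p_scores.columns]
    rna_hit = (g_scores[rna_cols] >= 2).any(axis=1)
    prot_hit = (p_scores[prot_cols] >= 1).any(axis=1)
    universe = g_scores.index
    prot_hit = prot_hit.reindex(universe).fillna(False)
    tf = tf_flags.reindex(universe).fillna(False).astype(bool)
    return universe[rna_hit & prot_hit & tf]


# --------------------------------------------------------------------------
# mutual information
# --------------------------------------------------------------------------


def _bin_count(n: int, n_bins: int | None) -> int:
    return n_bins if n_bins is not None else min(int(np.ceil(np.sqrt(n))), 10)


def _equal_frequency_bins(x: np.ndarray, b: int) -> np.ndarray:
    """Bin indices after rank transform; ties broken by stable order so
    every bin holds floor/ceil(n/b) points."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    bins = np.empty(n, dtype=np.int64)
    bins[order] = (np.arange(n) * b) // n
    return bins


def mutual_information(
    x: np.ndarray, y: np.ndarray, n_bins: int | None = None,
    williams: bool = False,
) -> tuple[float, float]:
    """Rank-based plug-in MI (nats) with a G-test p-value.

    Both vectors are rank-transformed and split into ``b`` equal-frequency
    bins, ``b = min(ceil(sqrt(n)), 10)`` by default; MI comes from the
    b x b contingency table and ``2 n MI ~ chi2((b-1)^2)`` under
    independence.  Constant vectors give MI 0, p 1.

    The plain G statistic is anti-conservative when ``n`` is small
    relative to ``b^2`` (its null mean exceeds the chi-square df);
    ``williams=True`` applies the Williams small-sample correction, which
    restores near-nominal type-I rates at the cost of a lighter extreme
    tail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 8 or len(y) != n:
        raise ValueError("need two equal-length vectors with n >= 8")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0, 1.0
    b = _bin_count(n, n_bins)
    bx = _equal_frequency_bins(x, b)
    by = _equal_frequency_bins(y, b)
    counts = np.zeros((b, b))
    np.add.at(counts, (bx, by), 1.0)
    p_xy = counts / n
    p_x = p_xy.sum(axis=1, keepdims=True)
    p_y = p_xy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p_xy * np.log(p_xy / (p_x * p_y))
    finite = terms[np.isfinite(terms)]
    # summing in sorted order makes MI(x, y) == MI(y, x) bit-exact
    mi = float(np.sort(finite, kind="stable").sum())
    mi = max(mi, 0.0)
    g = 2.0 * n * mi
    if williams:
        g /= _williams_q(n, b)
    p = float(scipy.stats.chi2.sf(g, df=(b - 1) ** 2))
    return mi, p


def _williams_q(n: int, b: int) -> float:
    # equal-frequency margins: n * sum(1/row_i) = b^2 on both axes
    return 1.0 + (b**2 - 1) ** 2 / (6.0 * n * (b - 1) ** 2)


def _mi_matrix(
    data: np.ndarray, hub_rows: np.ndarray, b: int
) -> tuple[np.ndarray, np.ndarray]:
    """MI (nats) of every hub row against every row; vectorized over the
    gene axis.  Returns (mi, p) with shape (n_hubs, n_genes)."""
    G, n = data.shape
    bins = np.empty((G, n), dtype=np.int64)
    for i in range(G):
        bins[i] = _equal_frequency_bins(data[i], b)
    mi = np.zeros((len(hub_rows), G))
    marg = np.zeros((G, b))
    np.add.at(marg, (np.repeat(np.arange(G), n), bins.ravel()), 1.0)
    marg /= n
    log_marg = np.where(marg > 0, np.log(marg), 0.0)
    for hi, h in enumerate(hub_rows):
        joint = np.zeros((G, b, b))
        gene_idx = np.repeat(np.arange(G), n)
        np.add.at(
            joint,
            (gene_idx, bins.ravel(), np.tile(bins[h], G)),
            1.0,
        )
        joint /= n
        with np.errstate(divide="ignore", invalid="ignore"):
            lj = np.where(joint > 0, np.log(joint), 0.0)
        ent = (joint * lj).sum(axis=(1, 2))
        hx = -(marg[h] * log_marg[h]).sum()
        hg = -(marg * log_marg).sum(axis=1)
        mi[hi] = np.maximum(ent + hg + hx, 0.0)
    df = (b - 1) ** 2
    p = scipy.stats.chi2.sf(2.0 * n * mi, df=df)
    return mi, p


# --------------------------------------------------------------------------
# network container and DPI
# --------------------------------------------------------------------------


@dataclass
class MINetwork:
    """Undirected hub-anchored MI network."""

    edges: pd.DataFrame  # node_a, node_b, weight (MI, nats), support
    hubs: pd.Index
    nodes: pd.Index
    window: str = "full"
    n_bootstraps: int = 0
    null_rate: float = np.nan

    def edge_set(self) -> set[tuple[str, str]]:
        return {
            tuple(sorted((a, b)))
            for a, b in zip(self.edges["node_a"], self.edges["node_b"])
        }


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def apply_dpi(
    edges: dict[tuple[str, str], float],
    hubs: set[str],
    tol: float = 0.1,
) -> dict[tuple[str, str], float]:
    """Data processing inequality pruning.

    For every connected triplet containing at least one hub, the edge
    (i, j) is marked for removal when
    ``MI_ij < (1 - tol) * min(MI_ik, MI_jk)``; marked edges are removed
    simultaneously.  With ``tol = 1`` nothing is ever removed.
    """
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    marked: set[tuple[str, str]] = set()
    factor = 1.0 - tol
    for k, neigh in adj.items():
        nlist = sorted(neigh)
        for i, j in itertools.combinations(nlist, 2):
            if j not in adj.get(i, ()):  # need the closing edge i-j
                continue
            if not (k in hubs or i in hubs or j in hubs):
                continue
            mi_ij = edges[_edge_key(i, j)]
            mi_ik = edges[_edge_key(i, k)]
            mi_jk = edges[_edge_key(j, k)]
            if mi_ij < factor * min(mi_ik, mi_jk):
                marked.add(_edge_key(i, j))
    return {e: w for e, w in edges.items() if e not in marked}


def reconstruct_network(
    matrix: AbundanceMatrix,
    hubs,
    design: SampleDesign | None = None,
    window: str = "full",
    n_bootstraps: int = 200,
    p_edge: float = 1e-10,
    dpi_tol: float = 0.1,
    p_consensus: float = 1e-8,
    n_bins: int | None = None,
    seed: int = 0,
) -> MINetwork:
    """Bootstrap consensus MI network between hubs and all other genes.

    Per bootstrap (samples resampled with replacement) hub-gene edges are
    kept at ``p < p_edge`` and DPI-pruned; a consensus edge must have
    bootstrap support k of B beating a binomial tail test against the
    pooled null support rate at ``p < p_consensus``.  Consensus MI is the
    mean over supporting bootstraps.
    """
    values = matrix.values
    if design is not None and window != "full":
        spec = WINDOWS[window]
        samples = [
            s
            for s in design.samples_in(groups=spec["groups"], times=spec["times"])
            if s in values.columns
        ]
        values = values[samples]
    n = values.shape[1]
    if n < 8:
        raise ValueError(f"window {window!r} selects only {n} samples (< 8)")

    genes = list(values.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    hubs = [h for h in hubs if h in gene_pos]
    if not hubs:
        raise ValueError("no hub present in the matrix")
    hub_rows = np.array([gene_pos[h] for h in hubs])
    hub_set = set(hubs)
    data = values.to_numpy(dtype=float)
    b = _bin_count(n, n_bins)
    rng = np.random.default_rng(seed)

    support: dict[tuple[str, str], int] = {}
    mi_sum: dict[tuple[str, str], float] = {}
    total_retained = 0
    for _ in range(n_bootstraps):
        idx = rng.integers(0, n, size=n)
        boot = data[:, idx]
        mi, p = _mi_matrix(boot, hub_rows, b)
        edges: dict[tuple[str, str], float] = {}
        for hi, h in enumerate(hubs):
            hits = np.where(p[hi] < p_edge)[0]
            for gi in hits:
                g = genes[gi]
                if g == h:
                    continue
                key = _edge_key(h, g)
                # hub-hub pairs are scored twice; keep the larger estimate
                edges[key] = max(edges.get(key, 0.0), mi[hi, gi])
        edges = apply_dpi(edges, hub_set, tol=dpi_tol)
        total_retained += len(edges)
        for key, w in edges.items():
            support[key] = support.get(key, 0) + 1
            mi_sum[key] = mi_sum.get(key, 0.0) + w

    n_candidates = len(hubs) * (len(genes) - 1) - (len(hubs) * (len(hubs) - 1)) // 2
    null_rate = total_retained / max(n_bootstraps * n_candidates, 1)
    rows = []
    for key, k in support.items():
        p_cons = scipy.stats.binom.sf(k - 1, n_bootstraps, max(null_rate, 1e-300))
        if p_cons < p_consensus:
            a, b_ = key
            rows.append(
                {
                    "node_a": a,
                    "node_b": b_,
                    "weight": mi_sum[key] / k,
                    "support": k,
                }
            )
    edges_df = pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "support"])
    nodes = pd.Index(
        sorted(set(edges_df["node_a"]) | set(edges_df["node_b"]) | hub_set)
    )
    return MINetwork(
        edges=edges_df,
        hubs=pd.Index(sorted(hub_set)),
        nodes=nodes,
        window=window,
        n_bootstraps=n_bootstraps,
        null_rate=null_rate,
    )


# --------------------------------------------------------------------------
# rewiring and subnetwork selection
# --------------------------------------------------------------------------


def union_networks(early: MINetwork, late: MINetwork) -> MINetwork:
    """Union of two networks; shared edges keep the larger MI weight."""
    merged: dict[tuple[str, str], dict] = {}
    for net in (early, late):
        for _, row in net.edges.iterrows():
            key = _edge_key(row["node_a"], row["node_b"])
            cur = merged.get(key)
            if cur is None or row["weight"] > cur["weight"]:
                merged[key] = {"weight": row["weight"], "support": row["support"]}
    rows = [
        {"node_a": a, "node_b": b, **v} for (a, b), v in sorted(merged.items())
    ]
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "support"])
    hubs = early.hubs.union(late.hubs)
    nodes = pd.Index(sorted(set(early.nodes) | set(late.nodes)))
    return MINetwork(edges=edges, hubs=hubs, nodes=nodes, window="full")


def _incident_weights(net: MINetwork) -> dict[str, dict[tuple[str, str], float]]:
    inc: dict[str, dict[tuple[str, str], float]] = {}
    for _, row in net.edges.iterrows():
        key = _edge_key(row["node_a"], row["node_b"])
        for node in key:
            inc.setdefault(node, {})[key] = float(row["weight"])
    return inc


def rewiring_scores(net_a: MINetwork, net_b: MINetwork) -> pd.Series:
    """Per-node rewiring score between two network states.

    For each node, the incident edges of both networks are united; the
    two incident-weight vectors (zero where an edge is absent) are
    normalized to unit sum (all-zero stays zero) and
    ``D_n = 1/2 * ||w_a - w_b||^2``.  Symmetric in its arguments; nodes
    absent from both networks are omitted.  Returned sorted decreasing.
    """
    inc_a = _incident_weights(net_a)
    inc_b = _incident_weights(net_b)
    scores = {}
    for node in sorted(set(inc_a) | set(inc_b)):
        ea = inc_a.get(node, {})
        eb = inc_b.get(node, {})
        keys = sorted(set(ea) | set(eb))
        wa = np.array([ea.get(k, 0.0) for k in keys])
        wb = np.array([eb.get(k, 0.0) for k in keys])
        if wa.sum() > 0:
            wa = wa / wa.sum()
        if wb.sum() > 0:
            wb = wb / wb.sum()
        scores[node] = 0.5 * float(((wa - wb) ** 2).sum())
    return pd.Series(scores, name="Dn").sort_values(ascending=False)


def select_subnetwork(
    net: MINetwork,
    deg: pd.DataFrame,
    anchor: str = "FOXP3",
    groups: tuple[str, ...] = ("G03", "G04", "G05", "G06"),
) -> MINetwork:
    """iTreg subnetwork: the anchor gene plus every node called DEG in all
    four iTreg conditions, with the induced edges of the (union) network.
    Unconnected selected nodes stay in the node list."""
    cols = [g for g in groups if g in deg.columns]
    values = deg[cols]
    if values.dtypes.apply(lambda d: d != bool).any():
        calls = values >= 2  # G scores: DEG iff >= 2 methods agree
    else:
        calls = values
    selected = set(deg.index[calls.all(axis=1)])
    if anchor in net.nodes or anchor in deg.index:
        selected.add(anchor)
    else:
        log.warning("anchor gene %r absent; proceeding without it", anchor)
    keep = net.edges[
        net.edges["node_a"].isin(selected) & net.edges["node_b"].isin(selected)
    ].reset_index(drop=True)
    nodes = pd.Index(sorted(selected & (set(net.nodes) | {anchor})))
    return MINetwork(
        edges=keep,
        hubs=pd.Index([h for h in net.hubs if h in selected]),
        nodes=nodes,
        window=net.window,
    )


def to_networkx(net: MINetwork):
    """Export as a networkx graph (node attribute ``is_hub``)."""
    import networkx as nx

    g = nx.Graph()
    for node in net.nodes:
        g.add_node(node, is_hub=bool(node in set(net.hubs)))
    for _, row in net.edges.iterrows():
        g.add_edge(
            row["node_a"], row["node_b"], weight=row["weight"], support=row["support"]
        )
    return g
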