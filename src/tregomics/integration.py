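"""RNA:protein integration and expression clustering.

Matched transcript/protein profiles are partitioned by differential-
expression status into four blocks, clustered, and summarized by per-gene
Spearman correlation.  Gene expression profiles are additionally grouped
by a Gaussian-mixture model (component count chosen by BIC, components
hierarchically merged by an entropy criterion), and cluster pairs are
connected by a permutation-tested mean-correlation statistic:

    beta = sum_i rho_i / s

over all s = n_a * n_b member-gene pairs, with the null built by
re-labelling the samples of the second cluster's profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# RNA:protein matching and blocks
# --------------------------------------------------------------------------


def match_rna_protein(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    gene_map: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair RNA and protein rows by gene id over shared samples.

    ``gene_map`` maps protein ids to gene ids (defaults to identity);
    multiple proteins mapping to one gene are averaged.  Returns
    (rna_paired, protein_paired) with identical gene index and the sample
    intersection as columns.
    """
    prot = protein.copy()
    if gene_map is not None:
        prot.index = gene_map.reindex(prot.index).to_numpy()
        prot = prot[~pd.isna(prot.index)]
    prot = prot.groupby(level=0).mean()
    genes = rna.index.intersection(prot.index)
    samples = rna.columns.intersection(prot.columns)
    if len(genes) == 0 or len(samples) == 0:
        raise ValueError("no shared genes/samples between RNA and protein data")
    return rna.loc[genes, samples], prot.loc[genes, samples]


BLOCK_NAMES = ("deg_dep", "deg_only", "dep_only", "neither")


def partition_blocks(deg: pd.Series, dep: pd.Series) -> dict[str, pd.Index]:
    """Exhaustive 2x2 partition of the shared gene universe by DEG/DEP."""
    universe = deg.index.intersection(dep.index)
    g = deg.reindex(universe).fillna(False).astype(bool)
    p = dep.reindex(universe).fillna(False).astype(bool)
    return {
        "deg_dep": universe[g & p],
        "deg_only": universe[g & ~p],
        "dep_only": universe[~g & p],
        "neither": universe[~g & ~p],
    }


# --------------------------------------------------------------------------
# hierarchical clustering of a block with silhouette/Dunn model selection
# --------------------------------------------------------------------------


def _dunn_index(dmat: np.ndarray, labels: np.ndarray) -> float:
    uniq = np.unique(labels)
    min_between = np.inf
    max_within = 0.0
    for a in uniq:
        ia = labels == a
        within = dmat[np.ix_(ia, ia)]
        if within.size > 1:
            max_within = max(max_within, within.max())
        for b in uniq:
            if b <= a:
                continue
            ib = labels == b
            min_between = min(min_between, dmat[np.ix_(ia, ib)].min())
    if max_within == 0:
        return np.inf
    return min_between / max_within


@dataclass
class BlockClustering:
    labels: pd.Series
    k: int
    silhouette: dict[int, float]
    dunn: dict[int, float]


def cluster_block(
    paired_z: pd.DataFrame, k_range: tuple[int, int] = (4, 10)
) -> BlockClustering:
    """Hierarchical clustering (Euclidean, complete linkage) of the
    concatenated RNA+protein z-profiles, cut at the k in ``k_range`` that
    maximizes average silhouette width (Dunn index breaking ties)."""
    k_min, k_max = k_range
    X = paired_z.to_numpy(dtype=float)
    if X.shape[0] < 2 * k_max:
        log.warning(
            "block has %d rows < 2*k_max=%d; falling back to k=2",
            X.shape[0],
            2 * k_max,
        )
        k_min = k_max = 2
    condensed = scipy.spatial.distance.pdist(X, metric="euclidean")
    dmat = scipy.spatial.distance.squareform(condensed)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="complete")
    sil: dict[int, float] = {}
    dunn: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        labels = scipy.cluster.hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        if len(np.unique(labels)) < 2:
            sil[k], dunn[k] = -1.0, 0.0
            continue
        sil[k] = float(silhouette_score(dmat, labels, metric="precomputed"))
        dunn[k] = float(_dunn_index(dmat, labels))
    best = max(sil, key=lambda k: (round(sil[k], 12), dunn[k]))
    return BlockClustering(
        labels=pd.Series(labels_by_k[best], index=paired_z.index, name="cluster"),
        k=best,
        silhouette=sil,
        dunn=dunn,
    )


def per_gene_spearman(
    rna_paired: pd.DataFrame, protein_paired: pd.DataFrame
) -> pd.Series:
    """Spearman correlation of each gene's RNA and protein profile over
    the shared samples; constant profiles yield NaN."""
    if rna_paired.shape[1] < 4:
        raise ValueError("need at least four shared samples")
    out = pd.Series(np.nan, index=rna_paired.index, name="spearman_rho")
    P = protein_paired.reindex(rna_paired.index)
    for g in rna_paired.index:
        x = rna_paired.loc[g].to_numpy(dtype=float)
        y = P.loc[g].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        out[g] = scipy.stats.spearmanr(x, y).statistic
    return out


def block_correlation_summary(
    rho: pd.Series, blocks: dict[str, pd.Index]
) -> pd.DataFrame:
    rows = []
    for name, genes in blocks.items():
        vals = rho.reindex(genes).dropna()
        rows.append(
            {
                "block": name,
                "n": len(vals),
                "median": float(vals.median()) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("block")


# --------------------------------------------------------------------------
# model-based clustering with entropy merging
# --------------------------------------------------------------------------


@dataclass
class ClusterModel:
    labels: pd.Series  # gene -> final cluster id (0-based)
    n_components: int  # mixture components selected by BIC
    n_clusters: int  # after hierarchical merging
    covariance_type: str
    bic: dict = field(default_factory=dict)
    mean_profiles: pd.DataFrame | None = None


def _merge_entropy(tau: np.ndarray, tol: float = 1e-3) -> np.ndarray:
    """Successively combine mixture components by the entropy criterion:
    at each step merge the pair whose union most reduces the total soft-
    assignment entropy, while the reduction exceeds ``tol`` nats per
    observation (well-separated components have near-zero confusion
    entropy and are never merged)."""

    def entropy(t):
        with np.errstate(divide="ignore", invalid="ignore"):
            e = -t * np.log(t)
        return float(np.nansum(e))

    tau = tau.copy()
    threshold = tol * tau.shape[0]
    while tau.shape[1] > 1:
        k = tau.shape[1]
        best_gain, best_pair = -np.inf, None
        col_ent = [entropy(tau[:, [j]]) for j in range(k)]
        for a in range(k):
            for b in range(a + 1, k):
                merged = tau[:, a] + tau[:, b]
                gain = col_ent[a] + col_ent[b] - entropy(merged[:, None])
                if gain > best_gain:
                    best_gain, best_pair = gain, (a, b)
        if best_gain <= threshold:
            break
        a, b = best_pair
        tau[:, a] += tau[:, b]
        tau = np.delete(tau, b, axis=1)
    return tau


def model_based_clusters(
    z: pd.DataFrame,
    component_range: tuple[int, int] = (2, 50),
    covariance_types: tuple[str, ...] = ("diag", "spherical"),
    merge_tol: float = 1e-3,
    seed: int = 0,
) -> ClusterModel:
    """Gaussian-mixture clustering of per-gene mean profiles.

    The component count in ``component_range`` and the covariance family
    are selected by BIC; the selected components are then hierarchically
    combined by the soft-assignment entropy criterion until merging stops
    paying.  Degenerate EM fits are retried with covariance
    regularization.
    """
    X = z.to_numpy(dtype=float)
    lo, hi = component_range
    hi = min(hi, X.shape[0] - 1)
    bics: dict[tuple[str, int], float] = {}
    best = None
    for cov in covariance_types:
        for k in range(lo, hi + 1):
            gm = GaussianMixture(
                n_components=k,
                covariance_type=cov,
                random_state=seed,
                n_init=1,
                reg_covar=1e-6,
            )
            try:
                gm.fit(X)
            except Exception:
                log.warning(
                    "EM degenerate for k=%d (%s); retrying regularized", k, cov
                )
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type=cov,
                    random_state=seed,
                    reg_covar=1e-2,
                )
                gm.fit(X)
            bic = gm.bic(X)
            bics[(cov, k)] = float(bic)
            if best is None or bic < best[0]:
                best = (bic, gm, cov, k)
    _, gm, cov, k = best
    tau = gm.predict_proba(X)
    tau_merged = _merge_entropy(tau, tol=merge_tol)
    labels = tau_merged.argmax(axis=1)
    # compact label ids
    uniq = {c: i for i, c in enumerate(pd.unique(labels))}
    labels = np.array([uniq[c] for c in labels])
    label_s = pd.Series(labels, index=z.index, name="cluster")
    profiles = z.groupby(label_s).mean()
    return ClusterModel(
        labels=label_s,
        n_components=k,
        n_clusters=len(uniq),
        covariance_type=cov,
        bic={f"{c}:{kk}": v for (c, kk), v in bics.items()},
        mean_profiles=profiles,
    )


# --------------------------------------------------------------------------
# permutation-tested cluster association
# --------------------------------------------------------------------------


@dataclass
class ClusterAssociation:
    beta: float
    p: float
    n_a: int
    n_b: int
    n_perm: int
    null_beta: np.ndarray


def _standardized_ranks(profiles: pd.DataFrame) -> np.ndarray:
    """Row-wise average ranks standardized to mean 0, population SD 1;
    constant rows become zero (they contribute zero correlation)."""
    X = profiles.to_numpy(dtype=float)
    R = np.apply_along_axis(scipy.stats.rankdata, 1, X)
    mu = R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf
    return (R - mu) / sd


def cluster_association(
    a_profiles: pd.DataFrame,
    b_profiles: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    add_one: bool = False,
) -> ClusterAssociation:
    """Mean pairwise Spearman correlation between two clusters with a
    sample-permutation p-value.

    ``beta`` averages the Spearman coefficients over all member-gene
    pairs; each permutation re-labels the samples of the second cluster's
    profiles and recomputes beta; ``p`` is the fraction of permuted
    |beta| values exceeding the observed |beta| (strict fraction, or the
    add-one convention ``(k+1)/(n+1)`` when ``add_one=True``).

    The pairwise-mean factorizes: with standardized rank profiles,
    ``beta = mean_A(z) . mean_B(z) / m``, so permutations only shuffle
    the mean profile of the permuted cluster.
    """
    m = a_profiles.shape[1]
    if m < 3 or b_profiles.shape[1] != m:
        raise ValueError("need >= 3 samples, identical and ordered, in both clusters")
    za = _standardized_ranks(a_profiles)
    zb = _standardized_ranks(b_profiles)
    ua = za.mean(axis=0)
    ub = zb.mean(axis=0)
    # deterministic orientation so that association(A, B) == association(B, A)
    if tuple(np.round(ub, 12)) < tuple(np.round(ua, 12)):
        ua, ub = ub, ua
    beta = float(ua @ ub / m)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = ua @ ub[rng.permutation(m)] / m
    exceed = int((np.abs(null) > abs(beta)).sum())
    p = (exceed + 1) / (n_perm + 1) if add_one else exceed / n_perm
    return ClusterAssociation(
        beta=beta,
        p=float(p),
        n_a=a_profiles.shape[0],
        n_b=b_profiles.shape[0],
        n_perm=n_perm,
        null_beta=null,
    )


def cluster_association_network(
    profiles_by_cluster: dict[int, pd.DataFrame],
    n_perm: int = 10000,
    seed: int = 0,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """All-pairs cluster association edge list (beta, p, sign,
    significant)."""
    ids = sorted(profiles_by_cluster)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            assoc = cluster_association(
                profiles_by_cluster[a], profiles_by_cluster[b], n_perm, seed
            )
            rows.append(
                {
                    "cluster_a": a,
                    "cluster_b": b,
                    "beta": assoc.beta,
                    "p": assoc.p,
                    "sign": "+" if assoc.beta >= 0 else "-",
                    "significant": assoc.p < p_threshold,
                }
            )
    return pd.DataFrame(rows)
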