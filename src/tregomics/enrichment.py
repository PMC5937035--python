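"""Gene-set enrichment machinery.

Three complementary tests: a 2x2 odds-ratio/hypergeometric test of a
query gene set against a category within a background; a resampling
enrichment in which the null odds-ratio distribution comes from redrawing
query-sized node sets from the background (with Westfall-Young step-down
minP family-wise error control over the category family); and preranked
GSEA with a weighted running-sum enrichment score and label-permutation
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats


# --------------------------------------------------------------------------
# odds ratio / hypergeometric
# --------------------------------------------------------------------------


@dataclass
class OddsRatioResult:
    a: int  # |query & category|
    b: int  # |query - category|
    c: int  # |category - query| (within background)
    d: int  # rest of background
    odds_ratio: float
    hypergeom_p: float
    haldane: bool = False


def odds_ratio(query, category, background) -> OddsRatioResult:
    """2x2 enrichment table of ``query`` vs ``category`` in ``background``.

    The odds ratio is (a*d)/(b*c) with the Haldane 0.5 correction applied
    to all cells iff any cell is zero; the hypergeometric p is the upper
    tail P(X >= a).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q = set(query) & bg
    if set(query) - bg:
        raise ValueError("query must be a subset of the background")
    cat = set(category) & bg
    a = len(q & cat)
    b = len(q - cat)
    c = len(cat - q)
    d = len(bg) - a - b - c
    cells = np.array([a, b, c, d], dtype=float)
    haldane = bool((cells == 0).any())
    if haldane:
        cells = cells + 0.5
    orr = float(cells[0] * cells[3] / (cells[1] * cells[2]))
    p = float(scipy.stats.hypergeom.sf(a - 1, len(bg), len(cat), len(q)))
    return OddsRatioResult(a, b, c, d, orr, p, haldane)


def _or_from_counts(a: np.ndarray, m: np.ndarray, k: int, n: int) -> np.ndarray:
    """Vectorized odds ratio for overlap counts ``a`` with category sizes
    ``m``, query size ``k``, background size ``n`` (Haldane on zeros)."""
    a = np.asarray(a, dtype=float)
    b = k - a
    c = m - a
    d = n - k - m + a
    z = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a, b, c, d = (x + 0.5 * z for x in (a, b, c, d))
    return (a * d) / (b * c)


# --------------------------------------------------------------------------
# resampling enrichment with step-down minP FWER
# --------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per category: a,b,c,d,odds_ratio,hypergeom_p,
    #                      resampling_p, fwer
    null_or: np.ndarray = field(repr=False, default=None)  # type: ignore
    n_resample: int = 0


def resampling_enrichment(
    query,
    catalog: dict,
    background,
    n_resample: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """Resampling-null enrichment over a catalog of categories.

    ``n_resample`` node sets of |query| size are drawn uniformly from the
    background; one shared draw per iteration serves every category (this
    preserves the cross-category dependence the minP procedure needs).
    The one-tailed p is the fraction of null odds ratios >= the observed
    one; FWER comes from the Westfall-Young step-down minimum-p procedure
    on the joint null p-value matrix, enforced monotone along the
    p-ordering.
    """
    bg = pd.Index(sorted(set(background)))
    n = len(bg)
    q = set(query)
    if len(q) > n:
        raise ValueError("query larger than background")
    names = list(catalog)
    cat_sets = {
        c: set(catalog[c]["genes"] if isinstance(catalog[c], dict) else catalog[c])
        & set(bg)
        for c in names
    }
    member = np.zeros((len(names), n), dtype=bool)
    pos = {g: i for i, g in enumerate(bg)}
    for ci, c in enumerate(names):
        for g in cat_sets[c]:
            member[ci, pos[g]] = True
    m_sizes = member.sum(axis=1)
    k = len(q & set(bg))

    obs = np.array(
        [
            odds_ratio(q & set(bg), cat_sets[c], bg).odds_ratio
            for c in names
        ]
    )
    rng = np.random.default_rng(seed)
    null_or = np.empty((n_resample, len(names)))
    for r in range(n_resample):
        draw = rng.choice(n, size=k, replace=False)
        a = member[:, draw].sum(axis=1)
        null_or[r] = _or_from_counts(a, m_sizes, k, n)

    # one-tailed p: fraction of null ORs >= observed
    res_p = (null_or >= obs[None, :]).mean(axis=0)
    # per-resample null p-values against the same null (rank-based)
    null_p = np.empty_like(null_or)
    for ci in range(len(names)):
        col = null_or[:, ci]
        # number of null values >= each value, as a fraction
        ranks = scipy.stats.rankdata(-col, method="max")
        null_p[:, ci] = ranks / n_resample

    order = np.argsort(res_p, kind="stable")
    fwer = np.empty(len(names))
    suffix_min = np.minimum.accumulate(null_p[:, order[::-1]], axis=1)[:, ::-1]
    for rank_i, ci in enumerate(order):
        fwer[ci] = (suffix_min[:, rank_i] <= res_p[ci]).mean()
    # enforce monotonicity down the ordering
    running = 0.0
    for ci in order:
        running = max(running, fwer[ci])
        fwer[ci] = running

    rows = []
    for ci, c in enumerate(names):
        t = odds_ratio(q & set(bg), cat_sets[c], bg)
        rows.append(
            {
                "category": c,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "odds_ratio": t.odds_ratio,
                "hypergeom_p": t.hypergeom_p,
                "resampling_p": res_p[ci],
                "fwer": fwer[ci],
            }
        )
    table = pd.DataFrame(rows).set_index("category")
    return EnrichmentResult(table=table, null_or=null_or, n_resample=n_resample)


def filter_weighted_catalog(
    catalog: dict[str, dict], scores: dict[str, dict[str, float]], min_score: float
) -> dict[str, dict]:
    """Drop category members whose association score falls below
    ``min_score`` (generic numeric-threshold filter for weighted
    catalogs)."""
    out = {}
    for name, entry in catalog.items():
        genes = entry["genes"] if isinstance(entry, dict) else list(entry)
        w = scores.get(name, {})
        kept = [g for g in genes if w.get(g, 0.0) >= min_score]
        if kept:
            out[name] = {"description": entry.get("description", "")
                         if isinstance(entry, dict) else "", "genes": kept}
    return out


# --------------------------------------------------------------------------
# preranked GSEA
# --------------------------------------------------------------------------


@dataclass
class GseaResult:
    es: float
    nes: float
    p: float
    leading_edge: list[str]
    n_perm: int


def _running_es(
    stats: np.ndarray, in_set: np.ndarray, weight: float
) -> tuple[float, int]:
    """Extremum of the weighted running sum (hit increments proportional
    to |stat|^weight, uniform miss decrements)."""
    w = np.abs(stats) ** weight
    hit_total = w[in_set].sum()
    if hit_total == 0:
        hit_total = 1.0
    n_miss = (~in_set).sum()
    steps = np.where(in_set, w / hit_total, -1.0 / n_miss)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if abs(running[i_max]) >= abs(running[i_min]):
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def preranked_gsea(
    statistic: pd.Series,
    gene_set,
    n_perm: int = 10000,
    weight: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Preranked gene-set enrichment analysis.

    Genes are ordered by decreasing statistic (e.g. -log10 p * sign of the
    fold change); the enrichment score is the extremum of the running sum;
    the null permutes the set-membership labels; the p-value is
    ``(1 + #{|ES_null| >= |ES|, same sign}) / (n_perm + 1)``; NES divides
    ES by the mean |same-sign null ES|.
    """
    if statistic.isna().any():
        raise ValueError("ranking statistic must have no missing values")
    stats = statistic.sort_values(ascending=False)
    genes = stats.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n_hit == len(genes):
        raise ValueError("gene set equals the ranked universe")
    vals = stats.to_numpy(dtype=float)
    es, i_ext = _running_es(vals, in_set, weight)

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    base = in_set.copy()
    for r in range(n_perm):
        null_es[r] = _running_es(vals, rng.permutation(base), weight)[0]
    same_sign = null_es * np.sign(es) > 0
    exceed = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    p = (1 + exceed) / (n_perm + 1)
    denom = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and np.isfinite(denom) else np.nan

    if es >= 0:
        le = genes[: i_ext + 1][in_set[: i_ext + 1]]
    else:
        le = genes[i_ext:][in_set[i_ext:]]
    return GseaResult(
        es=es, nes=float(nes), p=float(p), leading_edge=list(le), n_perm=n_perm
    )
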