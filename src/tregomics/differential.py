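"""Consensus time-course differential expression.

RNA counts are modeled per gene three ways — (1) a negative-binomial GLM
with time as a discrete factor, (2) a negative-binomial GLM with a natural
cubic spline of log-hours, and (3) stepwise cubic polynomial regression on
stabilized values — each including group main effects and group x time
interactions against the Mock-stimulated reference.  Per contrast
("time", or one iTreg group), the G score counts the methods calling the
gene significant; a gene is a DEG for the contrast when G >= 2.  Protein
log-ratios get a single linear model with empirical-Bayes-moderated
variances and binary P scores.

The model for counts is ``log mu = b0 + bG*x_G + bT*x_T + bGT*x_G*x_T``
with per-gene NB dispersion; a "coefficient category" (the group main
effect plus all its interactions, or all base time effects) is significant
when any member coefficient passes the BH-FDR threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .datamodel import AbundanceMatrix, CountMatrix, ProteinQuant, SampleDesign

log = logging.getLogger(__name__)

RNA_FDR = 0.01
PROTEIN_FDR = 0.05
R2_THRESHOLD = 0.7


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------


def natural_spline_basis(
    x: np.ndarray, df: int = 3, knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic spline basis (no intercept column), ``df`` columns.

    Knots are the boundary values plus ``df - 1`` internal quantiles of
    ``x``; the basis is linear beyond the boundaries (zero second
    derivative).
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        uniq = np.unique(x)
        probs = np.linspace(0, 1, df + 1)
        knots = np.quantile(uniq, probs)
    knots = np.unique(np.asarray(knots, dtype=float))
    if len(knots) != df + 1:
        raise ValueError(f"need {df + 1} distinct knots for df={df}")
    k_last = knots[-1]
    k_penult = knots[-2]

    def d(k: float) -> np.ndarray:
        return (
            np.clip(x - k, 0, None) ** 3 - np.clip(x - k_last, 0, None) ** 3
        ) / (k_last - k)

    cols = [x]
    for k in knots[:-2]:
        cols.append(d(k) - d(k_penult))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """Expanded design with named columns and coefficient categories."""

    X: np.ndarray
    columns: list[str]
    categories: dict[str, list[str]]  # contrast -> member coefficient names
    sample_ids: list[str]


def _log_hours(design: SampleDesign) -> np.ndarray:
    # hours span 2-144; log(hour + 1) keeps the early points resolved
    return np.log(design.hours.to_numpy() + 1.0)


def build_design(
    design: SampleDesign,
    time_coding: str = "discrete",
    reference_group: str = "G02",
    spline_df: int = 3,
    poly_degree: int = 3,
) -> DesignMatrix:
    """Design matrix with group, time and interaction terms.

    ``time_coding``: ``discrete`` (dummy per time point), ``spline``
    (natural cubic spline of log-hours) or ``poly`` (orthogonal-ish powers
    of centered log-hours).
    """
    t = design.table
    groups = sorted(t["group"].unique())
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group} absent from design")
    nonref = [g for g in groups if g != reference_group]

    if time_coding == "discrete":
        times = sorted(t["time"].unique())
        if len(times) < 2:
            raise ValueError("need at least two time points")
        tcols = {
            f"time[{tt}]": (t["time"] == tt).to_numpy(float) for tt in times[1:]
        }
    elif time_coding == "spline":
        lh = _log_hours(design)
        if len(np.unique(lh)) <= spline_df:
            raise ValueError("spline df must be below the number of time points")
        basis = natural_spline_basis(lh, df=spline_df)
        # re-express in orthonormal coordinates (same spline span): the raw
        # truncated-power columns are nearly collinear at a handful of
        # design hours, which would starve the per-coefficient Wald tests
        q, _ = np.linalg.qr(np.column_stack([np.ones(len(lh)), basis]))
        basis = q[:, 1:] * np.sqrt(len(lh))
        tcols = {f"stime{j + 1}": basis[:, j] for j in range(basis.shape[1])}
    elif time_coding == "poly":
        lh = _log_hours(design)
        z = (lh - lh.mean()) / lh.std()
        tcols = {f"t^{p}": z**p for p in range(1, poly_degree + 1)}
    else:
        raise ValueError(f"unknown time coding {time_coding!r}")

    columns = ["Intercept"]
    cols = [np.ones(len(t))]
    categories: dict[str, list[str]] = {"time": list(tcols)}
    for name, v in tcols.items():
        columns.append(name)
        cols.append(v)
    for g in nonref:
        gname = f"group[{g}]"
        gvec = (t["group"] == g).to_numpy(float)
        columns.append(gname)
        cols.append(gvec)
        members = [gname]
        for name, v in tcols.items():
            iname = f"{gname}:{name}"
            columns.append(iname)
            cols.append(gvec * v)
            members.append(iname)
        categories[g] = members
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after expansion")
    return DesignMatrix(
        X=X, columns=columns, categories=categories, sample_ids=list(t.index)
    )


# --------------------------------------------------------------------------
# per-method result container
# --------------------------------------------------------------------------


@dataclass
class MethodResult:
    """Per-gene p-values/FDRs per coefficient and per-contrast calls."""

    name: str
    pvalues: pd.DataFrame  # genes x coefficients
    fdr: pd.DataFrame
    significant: pd.DataFrame  # genes x contrasts (bool)
    extra: pd.DataFrame | None = None  # e.g. R2, LRT p


def _bh(pvals: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(np.nan, index=pvals.index, columns=pvals.columns)
    for c in pvals.columns:
        p = pvals[c].to_numpy()
        ok = np.isfinite(p)
        if ok.any():
            out.loc[ok, c] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _category_calls(
    fdr: pd.DataFrame, categories: dict[str, list[str]], threshold: float
) -> pd.DataFrame:
    sig = {}
    for contrast, members in categories.items():
        cols = [m for m in members if m in fdr.columns]
        sig[contrast] = (fdr[cols] < threshold).any(axis=1)
    return pd.DataFrame(sig)


# --------------------------------------------------------------------------
# negative-binomial GLMs (methods 1 and 2)
# --------------------------------------------------------------------------


def _nb_loglik_alpha(log_alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    a = np.exp(log_alpha)
    inv = 1.0 / a
    return -float(
        np.sum(
            scipy.special.gammaln(y + inv)
            - scipy.special.gammaln(inv)
            + y * np.log(a * mu / (1.0 + a * mu))
            - inv * np.log1p(a * mu)
        )
    )


def _estimate_alpha(y: np.ndarray, mu: np.ndarray, floor: float = 1e-8) -> float:
    """Per-gene ML dispersion given fitted means (profile likelihood)."""
    res = scipy.optimize.minimize_scalar(
        _nb_loglik_alpha,
        bounds=(np.log(floor), np.log(50.0)),
        args=(y, mu),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def _wald_pvalues(params: np.ndarray, bse: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse
    return 2.0 * scipy.stats.norm.sf(np.abs(z))


def _fit_nb_glm(
    counts: CountMatrix,
    design: SampleDesign,
    dm: DesignMatrix,
    name: str,
    size_factors: pd.Series | None = None,
    fdr_threshold: float = RNA_FDR,
    dispersion_floor: float = 1e-8,
    shrink_weight: float = 0.5,
    lrt: bool = False,
) -> MethodResult:
    from .transforms import size_factors as _sf

    if size_factors is None:
        size_factors = _sf(counts)
    Y = counts.values[dm.sample_ids].to_numpy(dtype=float)
    offset = np.log(size_factors.reindex(dm.sample_ids).to_numpy())
    genes = counts.values.index
    ncoef = len(dm.columns)
    X = dm.X

    # pass 1: Poisson fits give means for dispersion estimation
    alphas = np.full(len(genes), np.nan)
    mus = np.empty_like(Y)
    poisson = sm.families.Poisson()
    start = None
    for i in range(len(genes)):
        y = Y[i]
        if y.sum() == 0:
            mus[i] = np.exp(offset) * 1e-8
            alphas[i] = dispersion_floor
            continue
        try:
            res = sm.GLM(y, X, family=poisson, offset=offset).fit(
                maxiter=50, tol=1e-6, start_params=start
            )
            mus[i] = res.fittedvalues
        except Exception:
            mus[i] = np.maximum(y.mean(), 1e-8)
        alphas[i] = _estimate_alpha(y, np.maximum(mus[i], 1e-8), dispersion_floor)

    # mean-dispersion trend shrinkage (log-log linear trend, weight 0.5)
    base_mean = np.maximum(Y.mean(axis=1), 1e-8)
    ok = alphas > 10 * dispersion_floor
    if shrink_weight > 0 and ok.sum() >= 20:
        coefs = np.polyfit(np.log(base_mean[ok]), np.log(alphas[ok]), deg=1)
        trend = np.exp(np.polyval(coefs, np.log(base_mean)))
        alphas = np.exp(
            (1 - shrink_weight) * np.log(np.maximum(alphas, dispersion_floor))
            + shrink_weight * np.log(np.maximum(trend, dispersion_floor))
        )
    alphas = np.maximum(alphas, dispersion_floor)

    # pass 2: NB GLM with the per-gene dispersion, Wald tests
    pvals = np.full((len(genes), ncoef), np.nan)
    lrt_p = np.full(len(genes), np.nan)
    inter_cols = [
        j for j, c in enumerate(dm.columns) if ":" in c
    ]  # interaction columns, for the optional LRT
    X_reduced = np.delete(X, inter_cols, axis=1) if inter_cols else None
    n_fallback = 0
    for i in range(len(genes)):
        y = Y[i]
        if y.sum() == 0:
            pvals[i] = 1.0
            continue
        fam = sm.families.NegativeBinomial(alpha=alphas[i])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=fam, offset=offset).fit(
                    maxiter=50, tol=1e-6
                )
            if not np.all(np.isfinite(res.bse)):
                raise ValueError("non-finite standard errors")
        except Exception:
            n_fallback += 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=poisson, offset=offset).fit(
                    maxiter=50, tol=1e-6
                )
        pvals[i] = _wald_pvalues(res.params, res.bse)
        if lrt and X_reduced is not None:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    red = sm.GLM(y, X_reduced, family=fam, offset=offset).fit(
                        maxiter=50, tol=1e-6
                    )
                stat = 2.0 * (res.llf - red.llf)
                lrt_p[i] = scipy.stats.chi2.sf(max(stat, 0.0), df=len(inter_cols))
            except Exception:
                pass
    if n_fallback:
        log.warning(
            "%s: %d genes fell back to a Poisson fit", name, n_fallback
        )

    pdf = pd.DataFrame(pvals, index=genes, columns=dm.columns)
    fdr = _bh(pdf.drop(columns="Intercept"))
    sig = _category_calls(fdr, dm.categories, fdr_threshold)
    extra = pd.DataFrame({"dispersion": alphas}, index=genes)
    if lrt:
        extra["lrt_interaction_p"] = lrt_p
    return MethodResult(name=name, pvalues=pdf, fdr=fdr, significant=sig, extra=extra)


def fit_nb_glm_discrete(
    counts: CountMatrix,
    design: SampleDesign,
    reference_group: str = "G02",
    size_factors: pd.Series | None = None,
    fdr_threshold: float = RNA_FDR,
    lrt: bool = False,
) -> MethodResult:
    """Method (1): NB GLM with time as a discrete factor.

    Samples from the unstimulated controls (G01/G07) must be excluded by
    the caller; requires >= 2 time points per group.
    """
    _check_de_design(design)
    dm = build_design(design, "discrete", reference_group)
    return _fit_nb_glm(
        counts, design, dm, "nb_discrete", size_factors, fdr_threshold, lrt=lrt
    )


def fit_nb_glm_spline(
    counts: CountMatrix,
    design: SampleDesign,
    df: int = 3,
    reference_group: str = "G02",
    size_factors: pd.Series | None = None,
    fdr_threshold: float = RNA_FDR,
) -> MethodResult:
    """Method (2): NB GLM with a natural cubic spline of log-hours."""
    _check_de_design(design)
    n_times = design.table["time"].nunique()
    if df > n_times - 1:
        raise ValueError(f"spline df={df} too large for {n_times} time points")
    dm = build_design(design, "spline", reference_group, spline_df=df)
    return _fit_nb_glm(counts, design, dm, "nb_spline", size_factors, fdr_threshold)


def _check_de_design(design: SampleDesign) -> None:
    present = set(design.table["group"])
    if present & {"G01", "G07"}:
        raise ValueError(
            "exclude the unstimulated controls (G01, G07) before modeling"
        )
    counts_per_group = design.table.groupby("group")["time"].nunique()
    if (counts_per_group < 2).any():
        raise ValueError("every group needs at least two time points")


# --------------------------------------------------------------------------
# stepwise polynomial regression (method 3)
# --------------------------------------------------------------------------


def _ols_stats(X: np.ndarray, y: np.ndarray):
    """OLS coefficients, per-term p-values, R2 and global F-test p."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    dof = n - k
    if dof <= 0:
        return beta, np.full(k, np.nan), np.nan, np.nan
    s2 = rss / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tstat), dof)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if k > 1 and tss > rss and s2 > 0:
        f = ((tss - rss) / (k - 1)) / s2
        f_p = float(scipy.stats.f.sf(f, k - 1, dof))
    elif tss <= rss:
        f_p = 1.0
    else:
        f_p = np.nan
    return beta, pvals, r2, f_p


def fit_poly_stepwise(
    modlog_matrix: AbundanceMatrix,
    design: SampleDesign,
    degree: int = 3,
    reference_group: str = "G02",
    alpha: float = 0.05,
    fdr_threshold: float = RNA_FDR,
    r2_threshold: float = R2_THRESHOLD,
) -> MethodResult:
    """Method (3): per-gene cubic regression with backward stepwise
    elimination (alpha = 0.05) on stabilized values.

    The global F-test p of the full model is BH-adjusted across genes; a
    gene is significant when FDR < 0.01 and the best model's R2 > 0.7,
    with the time (group) contrast additionally requiring a retained base
    time (group-linked) term.
    """
    _check_de_design(design)
    dm = build_design(design, "poly", reference_group, poly_degree=degree)
    Y = modlog_matrix.values[dm.sample_ids].to_numpy(dtype=float)
    genes = modlog_matrix.values.index
    X_full = dm.X
    cols = dm.columns
    base_time = set(dm.categories["time"])

    full_p = np.full(len(genes), np.nan)
    best_r2 = np.full(len(genes), np.nan)
    retained: list[set[str]] = []
    for i in range(len(genes)):
        y = Y[i]
        _, _, r2_full, f_p = _ols_stats(X_full, y)
        full_p[i] = f_p
        keep = list(range(len(cols)))
        # backward elimination, intercept protected
        while len(keep) > 1:
            Xk = X_full[:, keep]
            _, pvals, r2_k, _ = _ols_stats(Xk, y)
            droppable = [(p, j) for j, p in zip(keep, pvals) if j != 0]
            worst_p, worst_j = max(droppable, key=lambda t: (np.nan_to_num(t[0], nan=1.0)))
            if np.isnan(worst_p) or worst_p > alpha:
                keep.remove(worst_j)
            else:
                break
        Xk = X_full[:, keep]
        _, _, r2_best, _ = _ols_stats(Xk, y)
        best_r2[i] = r2_best if len(keep) > 1 else 0.0
        retained.append({cols[j] for j in keep if j != 0})

    fdr_vals = np.full(len(genes), np.nan)
    okp = np.isfinite(full_p)
    if okp.any():
        fdr_vals[okp] = multipletests(full_p[okp], method="fdr_bh")[1]
    gate = (fdr_vals < fdr_threshold) & (best_r2 > r2_threshold)

    sig = {}
    sig["time"] = gate & np.array(
        [bool(r & base_time) for r in retained]
    )
    for contrast, members in dm.categories.items():
        if contrast == "time":
            continue
        mset = set(members)
        sig[contrast] = gate & np.array([bool(r & mset) for r in retained])
    sig_df = pd.DataFrame(sig, index=genes)
    extra = pd.DataFrame(
        {
            "full_model_p": full_p,
            "fdr": fdr_vals,
            "r2": best_r2,
            "retained_terms": [";".join(sorted(r)) for r in retained],
        },
        index=genes,
    )
    pdf = pd.DataFrame({"full_model": full_p}, index=genes)
    return MethodResult(
        name="poly_stepwise",
        pvalues=pdf,
        fdr=pd.DataFrame({"full_model": fdr_vals}, index=genes),
        significant=sig_df,
        extra=extra,
    )


# --------------------------------------------------------------------------
# consensus G scores
# --------------------------------------------------------------------------


@dataclass
class DEResult:
    """Consensus scores: per contrast the number of methods (of 3) calling
    the gene significant; DEG means score >= 2."""

    scores: pd.DataFrame  # genes x contrasts, integer 0..n_methods
    deg: pd.DataFrame  # genes x contrasts, bool (score >= 2)
    g_sum: pd.Series  # bool: DEG for at least one contrast
    n_methods: int = 3

    def shared_itreg_degs(self, groups=("G03", "G04", "G05", "G06")) -> pd.Index:
        cols = [g for g in groups if g in self.deg.columns]
        return self.deg.index[self.deg[cols].all(axis=1)]


def consensus_scores(results: list[MethodResult]) -> DEResult:
    """Combine per-method calls into G scores (DEG iff >= 2 methods)."""
    if not results:
        raise ValueError("no method results supplied")
    universe = results[0].significant.index
    contrasts = list(results[0].significant.columns)
    for r in results[1:]:
        if not r.significant.index.equals(universe):
            raise ValueError(f"gene universe mismatch between methods ({r.name})")
    scores = sum(
        r.significant[contrasts].astype(int) for r in results
    )
    deg = scores >= 2
    return DEResult(
        scores=scores,
        deg=deg,
        g_sum=deg.any(axis=1),
        n_methods=len(results),
    )


# --------------------------------------------------------------------------
# protein linear model with empirical-Bayes moderation
# --------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    tri = lambda x: scipy.special.polygamma(1, x)
    if y <= 0:
        return np.inf
    if y > tri(1e-6):
        return 1e-6
    return float(scipy.optimize.brentq(lambda x: tri(x) - y, 1e-6, 1e8))


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Fit the scaled inverse-chi-square prior (df0, s0^2) to observed
    residual variances by matching moments of log s^2."""
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(scipy.special.polygamma(1, df / 2.0))
    if evar > 0:
        df0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(
            np.exp(emean + scipy.special.digamma(df0 / 2.0) - np.log(df0 / 2.0))
        )
    else:
        df0 = np.inf
        s02 = float(np.exp(emean))
    return df0, s02


@dataclass
class ProteinDEResult:
    coefficients: pd.DataFrame
    moderated_t: pd.DataFrame
    pvalues: pd.DataFrame
    fdr: pd.DataFrame
    p_scores: pd.DataFrame  # binary per contrast
    p_sum: pd.Series
    prior_df: float = np.nan
    prior_var: float = np.nan


def fit_protein_lm(
    proteins: ProteinQuant,
    design: SampleDesign,
    groups: tuple[str, ...] = ("G02", "G03", "G05"),
    reference_group: str = "G02",
    fdr_threshold: float = PROTEIN_FDR,
    prior_df: float | None = None,
) -> ProteinDEResult:
    """Protein linear model: group + discrete time + interactions, with
    residual variances shrunk toward an inverse-gamma prior fitted to
    their distribution (moderated t, augmented degrees of freedom).

    Only proteins quantified in all modeled samples enter; technical
    replicates are averaged per (donor, group, time) first.  ``prior_df``
    overrides the estimated prior: 0 recovers the ordinary t-test, large
    values pull every variance to the common prior value.
    """
    samples = design.samples_in(groups=groups)
    samples = [s for s in samples if s in proteins.log2r.columns]
    if len(samples) < 4:
        raise ValueError("too few proteome samples for the linear model")
    sub = design.subset(samples)
    mat = proteins.log2r[samples]
    # average technical replicates per biological condition
    if sub.table["technical_replicate"].nunique() > 1:
        key = sub.table[["donor", "group", "time"]].astype(str).agg("_".join, axis=1)
        mat = mat.T.groupby(key).mean().T
        first = sub.table.groupby(key).head(1)
        first = first.set_index(
            first[["donor", "group", "time"]].astype(str).agg("_".join, axis=1)
        )
        sub = SampleDesign(first.loc[mat.columns])
        mat.columns = sub.table.index

    complete = mat.notna().all(axis=1)
    mat = mat.loc[complete]
    if mat.empty:
        raise ValueError("no protein is quantified in all modeled samples")

    dm = build_design(sub, "discrete", reference_group)
    X = dm.X
    Y = mat[dm.sample_ids].to_numpy(dtype=float)
    n, k = X.shape
    dof = n - k
    if dof <= 0:
        raise ValueError("protein design has no residual degrees of freedom")

    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T  # proteins x coefficients
    resid = Y - B @ X.T
    s2 = (resid**2).sum(axis=1) / dof
    XtX_inv_diag = np.diag(np.linalg.pinv(X.T @ X))

    if prior_df is None:
        df0, s02 = fit_variance_prior(s2, dof)
    else:
        df0 = float(prior_df)
        _, s02 = fit_variance_prior(s2, dof)
    if np.isinf(df0):
        s2_post = np.full_like(s2, s02)
    elif df0 == 0:
        s2_post = s2
    else:
        s2_post = (df0 * s02 + dof * s2) / (df0 + dof)
    df_total = min(df0 + dof, 1e9)

    se = np.sqrt(np.outer(s2_post, XtX_inv_diag))
    with np.errstate(divide="ignore", invalid="ignore"):
        tmat = B / se
    pmat = 2.0 * scipy.stats.t.sf(np.abs(tmat), df_total)

    coef_df = pd.DataFrame(B, index=mat.index, columns=dm.columns)
    t_df = pd.DataFrame(tmat, index=mat.index, columns=dm.columns)
    p_df = pd.DataFrame(pmat, index=mat.index, columns=dm.columns)
    fdr = _bh(p_df.drop(columns="Intercept"))
    calls = _category_calls(fdr, dm.categories, fdr_threshold)
    p_scores = calls.astype(int)
    return ProteinDEResult(
        coefficients=coef_df,
        moderated_t=t_df,
        pvalues=p_df,
        fdr=fdr,
        p_scores=p_scores,
        p_sum=(p_scores > 0).any(axis=1),
        prior_df=df0,
        prior_var=s02,
    )
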