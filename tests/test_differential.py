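"""Consensus differential expression: spline basis construction, the
three RNA methods, G-score consensus, and the moderated protein model."""

import numpy as np
import pandas as pd
import pytest
import scipy.interpolate
import scipy.stats

from tregomics import CountMatrix, SampleDesign, SimConfig, generate_counts, modlog
from tregomics.datamodel import AbundanceMatrix
from tregomics.differential import (
    MethodResult,
    build_design,
    consensus_scores,
    fit_nb_glm_discrete,
    fit_nb_glm_spline,
    fit_poly_stepwise,
    fit_protein_lm,
    natural_spline_basis,
    _ols_stats,
)


def _tiny_design(n_donors=3, groups=("G02", "G03"), times=("T02", "T03", "T04", "T05", "T06")):
    rows = []
    for d in range(n_donors):
        for g in groups:
            for t in times:
                rows.append(
                    {"sample_id": f"D{d}_{g}_{t}", "donor": f"D{d}", "group": g,
                     "time": t}
                )
    return SampleDesign(pd.DataFrame(rows).set_index("sample_id"))


# --------------------------------------------------------------------------
# natural spline basis
# --------------------------------------------------------------------------


def test_spline_basis_spans_natural_splines():
    """Any natural cubic spline through the knots is reproduced exactly by
    intercept + basis (independent construction via scipy's natural
    spline interpolator)."""
    x = np.log(np.array([2.0, 6.0, 24.0, 48.0, 144.0]) + 1)
    basis = natural_spline_basis(x, df=3)
    assert basis.shape == (5, 3)
    uniq = np.unique(x)
    knots = np.quantile(uniq, np.linspace(0, 1, 4))
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(len(x)), basis])
    for _ in range(5):
        y_at_knots = rng.normal(size=len(knots))
        cs = scipy.interpolate.CubicSpline(knots, y_at_knots, bc_type="natural")
        y = cs(x)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(resid).max() < 1e-8


def test_spline_basis_linear_beyond_boundaries():
    x = np.linspace(0, 10, 40)
    basis = natural_spline_basis(x, df=3, knots=np.array([2.0, 4.0, 6.0, 8.0]))
    outside = np.concatenate([np.linspace(-5, 1.9, 20), np.linspace(8.1, 15, 20)])
    b_out = natural_spline_basis(outside, df=3, knots=np.array([2.0, 4.0, 6.0, 8.0]))
    # second differences vanish on each side of the boundary knots
    left = b_out[:20]
    right = b_out[20:]
    for seg in (left, right):
        second = np.diff(seg, n=2, axis=0)
        assert np.abs(second).max() < 1e-8


# --------------------------------------------------------------------------
# constant genes are never significant
# --------------------------------------------------------------------------


def test_constant_gene_not_significant():
    design = _tiny_design()
    n = len(design.table)
    vals = pd.DataFrame(
        {s: [50, 200] for s in design.sample_ids}, index=["flat1", "flat2"]
    )
    counts = CountMatrix(vals)
    m1 = fit_nb_glm_discrete(counts, design)
    m2 = fit_nb_glm_spline(counts, design)
    m3 = fit_poly_stepwise(modlog(counts, factors=pd.Series(1.0, index=design.sample_ids)), design)
    for m in (m1, m2, m3):
        assert not m.significant.to_numpy().any()


def test_design_excludes_unstimulated_controls():
    rows = [
        {"sample_id": f"s{i}", "donor": f"D{i}", "group": "G01", "time": "T01"}
        for i in range(3)
    ]
    rows += [
        {"sample_id": f"t{i}", "donor": f"D{i}", "group": "G02", "time": "T02"}
        for i in range(3)
    ]
    design = SampleDesign(pd.DataFrame(rows).set_index("sample_id"))
    counts = CountMatrix(
        pd.DataFrame(
            np.ones((2, 6), dtype=int) * 10,
            index=["a", "b"],
            columns=design.sample_ids,
        )
    )
    with pytest.raises(ValueError, match="G01"):
        fit_nb_glm_discrete(counts, design)


# --------------------------------------------------------------------------
# null calibration and power (simulation oracles)
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def power_sim():
    """120 genes: 30 with a planted G03 group x time effect of 2 log2
    units at >= 2 time points, 90 null; phi = 0.05, 3 donors."""
    cfg = SimConfig(
        n_genes=120,
        seed=21,
        groups=("G02", "G03"),
        frac_time_de=0.0,
        frac_itreg_de={"G03": 0.25},
        frac_shared_core=0.0,
        n_hubs=0,
        frac_leg=0.0,
        effect_size_log2=2.0,
        nb_dispersion=0.05,
    )
    counts, design, truth = generate_counts(cfg)
    return counts, design, truth


def test_nb_discrete_power(power_sim):
    counts, design, truth = power_sim
    res = fit_nb_glm_discrete(counts, design)
    planted = truth.genes["itreg_de_G03"]
    assert res.significant.loc[planted, "G03"].mean() >= 0.9
    # single-method asymptotic Wald tests are mildly liberal at n=30; the
    # two-of-three consensus is what controls the final false-call rate
    assert res.significant.loc[~planted, "G03"].mean() <= 0.10


def test_nb_spline_power_close_to_discrete(power_sim):
    counts, design, truth = power_sim
    r1 = fit_nb_glm_discrete(counts, design)
    r2 = fit_nb_glm_spline(counts, design)
    planted = truth.genes["itreg_de_G03"]
    p1 = r1.significant.loc[planted, "G03"].mean()
    p2 = r2.significant.loc[planted, "G03"].mean()
    assert p2 >= p1 - 0.10


def test_nb_discrete_null_calibration():
    cfg = SimConfig(
        n_genes=300,
        seed=33,
        groups=("G02", "G03"),
        frac_time_de=0.0,
        frac_itreg_de={"G03": 0.0},
        frac_shared_core=0.0,
        n_hubs=0,
        frac_leg=0.0,
    )
    counts, design, _ = generate_counts(cfg)
    res = fit_nb_glm_discrete(counts, design)
    # raw per-coefficient p-values behave like a (mildly liberal,
    # asymptotic-Wald) null sample
    pvals = res.pvalues.drop(columns="Intercept").to_numpy().ravel()
    assert 0.01 < (pvals < 0.05).mean() < 0.15
    # and essentially nothing survives FDR < 0.01
    assert res.significant.to_numpy().mean() <= 0.02


# --------------------------------------------------------------------------
# stepwise polynomial method
# --------------------------------------------------------------------------


def test_noiseless_cubic_r2_one():
    design = _tiny_design(groups=("G02", "G03"))
    lh = np.log(design.hours.to_numpy() + 1.0)
    z = (lh - lh.mean()) / lh.std()
    y = 1.0 + 0.5 * z - 0.3 * z**2 + 0.2 * z**3
    mat = AbundanceMatrix(
        pd.DataFrame([y], index=["cubic"], columns=design.sample_ids)
    )
    res = fit_poly_stepwise(mat, design)
    assert res.extra.loc["cubic", "r2"] == pytest.approx(1.0, abs=1e-9)
    retained = res.extra.loc["cubic", "retained_terms"]
    for term in ("t^1", "t^2", "t^3"):
        assert term in retained


def test_pure_noise_rarely_significant(rng):
    design = _tiny_design(groups=("G02", "G03"))
    n = len(design.table)
    vals = rng.normal(0, 1, size=(200, n))
    mat = AbundanceMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(200)],
                     columns=design.sample_ids)
    )
    res = fit_poly_stepwise(mat, design)
    assert res.significant.to_numpy().any(axis=1).mean() <= 0.05


def test_stepwise_matches_best_subset():
    """On a 3-term toy model, backward elimination lands on the same term
    set as exhaustive search for the best all-significant submodel."""
    rng = np.random.default_rng(2)
    n = 40
    t1, t2, t3 = rng.normal(size=(3, n))
    X_terms = {"t1": t1, "t2": t2, "t3": t3}
    y = 2.0 * t1 - 1.5 * t2 + rng.normal(0, 0.5, n)

    import itertools

    alpha = 0.05
    best_subset, best_r2 = None, -np.inf
    for r in range(1, 4):
        for combo in itertools.combinations(X_terms, r):
            X = np.column_stack([np.ones(n)] + [X_terms[c] for c in combo])
            _, pvals, r2, _ = _ols_stats(X, y)
            if (pvals[1:] <= alpha).all() and r2 > best_r2:
                best_subset, best_r2 = set(combo), r2

    # backward elimination with the same alpha
    keep = list(X_terms)
    while keep:
        X = np.column_stack([np.ones(n)] + [X_terms[c] for c in keep])
        _, pvals, _, _ = _ols_stats(X, y)
        worst = np.argmax(pvals[1:])
        if pvals[1 + worst] > alpha:
            keep.pop(worst)
        else:
            break
    assert set(keep) == best_subset == {"t1", "t2"}


# --------------------------------------------------------------------------
# consensus scores
# --------------------------------------------------------------------------


def _method(name, sig: dict) -> MethodResult:
    df = pd.DataFrame(sig)
    return MethodResult(
        name=name,
        pvalues=pd.DataFrame(index=df.index),
        fdr=pd.DataFrame(index=df.index),
        significant=df,
    )


def test_consensus_counting():
    idx = ["g1", "g2", "g3"]
    m1 = _method("a", {"time": pd.Series([True, False, True], index=idx),
                       "G03": pd.Series([True, False, True], index=idx)})
    m2 = _method("b", {"time": pd.Series([True, False, False], index=idx),
                       "G03": pd.Series([True, True, True], index=idx)})
    m3 = _method("c", {"time": pd.Series([False, True, False], index=idx),
                       "G03": pd.Series([False, False, True], index=idx)})
    res = consensus_scores([m1, m2, m3])
    # significant in two methods -> DEG
    assert res.scores.loc["g1", "G03"] == 2 and res.deg.loc["g1", "G03"]
    # significant in one method only -> not a DEG
    assert res.scores.loc["g2", "G03"] == 1 and not res.deg.loc["g2", "G03"]
    # significant in all three
    assert res.scores.loc["g3", "G03"] == 3 and res.deg.loc["g3", "G03"]
    assert res.g_sum.tolist() == [True, False, True]


def test_consensus_monotone_in_methods():
    """Adding a significant method never removes a DEG call."""
    idx = ["g1", "g2"]
    m1 = _method("a", {"G03": pd.Series([True, False], index=idx)})
    m2 = _method("b", {"G03": pd.Series([True, False], index=idx)})
    extra = _method("c", {"G03": pd.Series([True, True], index=idx)})
    before = consensus_scores([m1, m2]).deg["G03"]
    after = consensus_scores([m1, m2, extra]).deg["G03"]
    assert (after | ~before).all()


def test_consensus_rejects_mismatched_universe():
    m1 = _method("a", {"G03": pd.Series([True], index=["g1"])})
    m2 = _method("b", {"G03": pd.Series([True], index=["g2"])})
    with pytest.raises(ValueError, match="universe"):
        consensus_scores([m1, m2])


# --------------------------------------------------------------------------
# protein linear model
# --------------------------------------------------------------------------


def _protein_design():
    rows = []
    for d in range(3):
        for g in ("G02", "G03", "G05"):
            for t in ("T03", "T04", "T05", "T06"):
                rows.append(
                    {"sample_id": f"D{d}_{g}_{t}", "donor": f"D{d}", "group": g,
                     "time": t}
                )
    return SampleDesign(pd.DataFrame(rows).set_index("sample_id"))


def test_constant_protein_scores_zero():
    design = _protein_design()
    from tregomics import ProteinQuant

    rng = np.random.default_rng(0)
    vals = np.vstack(
        [np.zeros(len(design.table)), rng.normal(0, 0.3, len(design.table))]
    )
    pq = ProteinQuant(
        pd.DataFrame(vals, index=["flat", "noise"], columns=design.sample_ids)
    )
    res = fit_protein_lm(pq, design)
    assert (res.p_scores.loc["flat"] == 0).all()


def test_zero_prior_df_recovers_ordinary_t():
    design = _protein_design()
    from tregomics import ProteinQuant

    rng = np.random.default_rng(3)
    vals = rng.normal(0, 0.5, size=(30, len(design.table)))
    pq = ProteinQuant(
        pd.DataFrame(vals, index=[f"P{i}" for i in range(30)],
                     columns=design.sample_ids)
    )
    res = fit_protein_lm(pq, design, prior_df=0)
    # ordinary t for one protein, one coefficient, by direct OLS
    dm = build_design(design.subset(design.sample_ids), "discrete", "G02")
    X = dm.X
    y = vals[0]
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(np.diag(np.linalg.pinv(X.T @ X)) * s2)
    t_manual = beta / se
    assert res.moderated_t.iloc[0].to_numpy() == pytest.approx(t_manual)


def test_protein_planted_effect_power():
    """A 1.5-log2 group x time effect with sd 0.2 is called P_G03=1 for
    nearly all planted proteins."""
    design = _protein_design()
    from tregomics import ProteinQuant

    rng = np.random.default_rng(11)
    n = len(design.table)
    hours = design.hours.to_numpy()
    is_g03 = (design.table["group"] == "G03").to_numpy()
    prots, planted = [], []
    for i in range(60):
        base = rng.normal(0, 0.2, n)
        if i < 20:
            base = base + 1.5 * (is_g03 & (hours >= 24))
            planted.append(f"P{i}")
        prots.append(base)
    pq = ProteinQuant(
        pd.DataFrame(prots, index=[f"P{i}" for i in range(60)],
                     columns=design.sample_ids)
    )
    res = fit_protein_lm(pq, design)
    assert res.p_scores.loc[planted, "G03"].mean() >= 0.9
    nulls = [f"P{i}" for i in range(20, 60)]
    assert res.p_scores.loc[nulls, "G03"].mean() <= 0.1


def test_protein_with_missing_sample_excluded():
    design = _protein_design()
    from tregomics import ProteinQuant

    rng = np.random.default_rng(5)
    vals = pd.DataFrame(
        rng.normal(0, 0.3, size=(3, len(design.table))),
        index=["ok1", "ok2", "gap"],
        columns=design.sample_ids,
    )
    vals.iloc[2, 0] = np.nan
    pq = ProteinQuant(vals)
    res = fit_protein_lm(pq, design)
    assert "gap" not in res.p_scores.index
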