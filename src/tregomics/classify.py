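"""Pairwise discriminant classification screens.

Every unordered pair of genes from a candidate list is used as a
two-feature linear discriminant classifier of iTreg versus
Mock-stimulated samples, with shrinkage-regularized covariance ("auto"
regularization) and stratified five-fold cross-validation, repeated in
two runs differing only in fold assignment.  A bagged-tree ensemble with
out-of-bag permutation importance ranks all expressed genes as an
unbiased complement.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)


def enumerate_pairs(
    genes, runs: int = 2
) -> tuple[list[tuple[str, str]], int]:
    """All unordered pairs of distinct genes and the total number of
    classifier evaluations (``runs * C(n, 2)``)."""
    seen = list(dict.fromkeys(genes))
    if len(seen) < len(list(genes)):
        log.warning("duplicate genes in list; de-duplicated")
    if len(seen) < 2:
        raise ValueError("need at least two unique genes")
    pairs = list(itertools.combinations(seen, 2))
    return pairs, runs * len(pairs)


@dataclass
class ClassifierReport:
    gene_a: str
    gene_b: str
    accuracies: tuple[float, ...]  # one per run
    n_folds: int
    n_runs: int


def lda_cv(
    X: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    runs: int = 2,
    seed: int = 0,
    gene_pair: tuple[str, str] = ("gene_a", "gene_b"),
) -> ClassifierReport:
    """Cross-validated two-class LDA accuracy for one feature pair.

    The shared covariance is shrunk toward its diagonal with the
    analytically chosen (Ledoit-Wolf) intensity; stratified k-fold CV
    guarantees both classes in every training fold; runs differ only in
    the fold-assignment seed.  If a class is smaller than ``folds`` the
    fold count is reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    min_class = int(counts.min())
    if min_class < folds:
        log.warning("smallest class has %d members; folds reduced", min_class)
        folds = max(2, min_class)
    accs = []
    for run in range(runs):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + run)
        correct = 0
        for train, test in skf.split(X, labels):
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            Xtr = X[train]
            if np.allclose(Xtr.std(axis=0), 0):
                # degenerate constant features: predict the majority class
                vals, cnts = np.unique(labels[train], return_counts=True)
                pred = np.full(len(test), vals[np.argmax(cnts)])
            else:
                clf.fit(Xtr, labels[train])
                pred = clf.predict(X[test])
            correct += int((pred == labels[test]).sum())
        accs.append(correct / len(labels))
    return ClassifierReport(
        gene_a=gene_pair[0],
        gene_b=gene_pair[1],
        accuracies=tuple(accs),
        n_folds=folds,
        n_runs=runs,
    )


def pairwise_lda_screen(
    matrix: pd.DataFrame,
    labels: pd.Series,
    genes,
    folds: int = 5,
    runs: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """LDA screen over every gene pair from ``genes``.

    ``matrix`` is genes x samples; ``labels`` maps sample to class
    (positive = iTreg, negative = control).  Returns one row per pair
    with per-run accuracies.
    """
    pairs, _ = enumerate_pairs(genes)
    y = labels.loc[matrix.columns].to_numpy()
    rows = []
    for a, b in pairs:
        X = matrix.loc[[a, b]].to_numpy(dtype=float).T
        rep = lda_cv(X, y, folds=folds, runs=runs, seed=seed, gene_pair=(a, b))
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                **{f"acc_run{r + 1}": acc for r, acc in enumerate(rep.accuracies)},
            }
        )
    return pd.DataFrame(rows)


def top_classifiers(
    reports: pd.DataFrame, accuracy_threshold: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairs meeting the accuracy threshold in every run, plus the
    per-gene frequency of appearances among the selected pairs."""
    acc_cols = [c for c in reports.columns if c.startswith("acc_run")]
    keep = reports[(reports[acc_cols] >= accuracy_threshold).all(axis=1)].copy()
    freq = (
        pd.concat([keep["gene_a"], keep["gene_b"]])
        .value_counts()
        .rename("n_selected_pairs")
    )
    return keep.reset_index(drop=True), freq


def rf_rank(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    max_features: str | int = "sqrt",
) -> pd.DataFrame:
    """Rank genes by out-of-bag permutation importance of a bagged-tree
    ensemble.

    Each tree is grown on a bootstrap of the samples; its out-of-bag
    error is measured before and after permuting one feature's values;
    the importance is the mean error increase over trees.  Ties are
    broken by gene id for determinism.
    """
    y = labels.loc[matrix.columns].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    n, p = X.shape
    rng = np.random.default_rng(seed)
    delta = np.zeros(p)
    used = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(2**31))
        )
        tree.fit(X[boot], y[boot])
        base_err = float((tree.predict(X[oob]) != y[oob]).mean())
        feat_used = np.unique(tree.tree_.feature)
        feat_used = feat_used[feat_used >= 0]
        for j in feat_used:
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            err = float((tree.predict(Xp) != y[oob]).mean())
            delta[j] += err - base_err
            used[j] += 1
        # unused features contribute zero importance for this tree
        unused = np.setdiff1d(np.arange(p), feat_used)
        used[unused] += 1
    with np.errstate(invalid="ignore"):
        importance = np.where(used > 0, delta / np.maximum(used, 1), 0.0)
    out = pd.DataFrame(
        {"gene": matrix.index, "importance": importance}
    ).sort_values(["importance", "gene"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


def itreg_labels(
    design, positive_groups=("G03", "G04", "G05", "G06"), negative_group="G02"
) -> pd.Series:
    """Binary labels: 1 for iTreg-protocol samples, 0 for Mock control;
    other groups are excluded (NaN)."""
    g = design.table["group"]
    lab = pd.Series(np.nan, index=design.table.index, name="label")
    lab[g.isin(positive_groups)] = 1.0
    lab[g == negative_group] = 0.0
    return lab
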