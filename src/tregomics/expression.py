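"""Expressed-gene thresholding and expression-level utilities.

Bulk RNA-seq log2(FPKM) values are bimodal: a low mode of lowly expressed,
putatively non-functional genes (LEGs) and a high mode of highly expressed
genes (HEGs).  The threshold separating them is estimated per treatment
group with a two-component Gaussian mixture on per-gene group means, and
the global cut ``t`` is the average of the per-group midpoints between the
two classified components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .datamodel import AbundanceMatrix, SampleDesign

AVOGADRO = 6.02214076e23


@dataclass
class ExpressionThreshold:
    """Per-group LEG/HEG midpoints and their mean ``t`` (log2 FPKM)."""

    midpoints: dict[str, float]
    t: float
    min_samples: int = 15


class MixtureFitError(RuntimeError):
    pass


def _group_midpoint(values: np.ndarray, group: str, seed: int) -> float:
    """Midpoint between the LEG and HEG components of a 1-D two-component
    unequal-variance Gaussian mixture fitted by EM (k-means init, 10
    restarts, tol 1e-6)."""
    x = values[np.isfinite(values)].reshape(-1, 1)
    if len(x) < 10:
        raise MixtureFitError(f"group {group}: too few finite values for a mixture")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=10,
        init_params="kmeans",
        tol=1e-6,
        random_state=seed,
    )
    try:
        gm.fit(x)
    except Exception as err:  # pragma: no cover - sklearn internal failures
        raise MixtureFitError(f"group {group}: EM failed ({err})") from err
    labels = gm.predict(x)
    means = gm.means_.ravel()
    if len(np.unique(labels)) < 2:
        raise MixtureFitError(f"group {group}: degenerate single-component fit")
    low, high = np.argsort(means)
    leg_max = x[labels == low].max()
    heg_min = x[labels == high].min()
    return float((leg_max + heg_min) / 2.0)


def fit_heg_threshold(
    log2fpkm: AbundanceMatrix,
    design: SampleDesign,
    groups=("G02", "G03", "G04", "G05", "G06"),
    min_samples: int = 15,
    seed: int = 0,
) -> ExpressionThreshold:
    """Fit the HEG/LEG expression threshold.

    Per group, genes are aggregated as their mean log2(FPKM) over that
    group's samples, a two-component unequal-variance Gaussian mixture is
    fitted, and the midpoint between the maximum LEG-classified and
    minimum HEG-classified value is taken; ``t`` is the mean of the
    per-group midpoints.
    """
    present = [g for g in groups if (design.table["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("need samples from at least two groups")
    midpoints: dict[str, float] = {}
    for g in present:
        samples = design.samples_in(groups=[g])
        samples = [s for s in samples if s in log2fpkm.values.columns]
        means = log2fpkm.values[samples].mean(axis=1).to_numpy()
        midpoints[g] = _group_midpoint(means, g, seed)
    t = float(np.mean(list(midpoints.values())))
    return ExpressionThreshold(midpoints=midpoints, t=t, min_samples=min_samples)


def classify_expressed(
    log2fpkm: AbundanceMatrix, threshold: ExpressionThreshold
) -> pd.Index:
    """Genes with log2(FPKM) > t in at least ``min_samples`` samples."""
    n_samples = log2fpkm.values.shape[1]
    if threshold.min_samples > n_samples:
        raise ValueError(
            f"min_samples={threshold.min_samples} exceeds {n_samples} samples"
        )
    above = (log2fpkm.values > threshold.t).sum(axis=1)
    return log2fpkm.values.index[above >= threshold.min_samples]


def rna_level_category(mean_count: float) -> str:
    """Coarse RNA expression category from the mean raw count:
    ``+`` < 100, ``++`` 100–1000, ``+++`` 1000 and above (boundaries go to
    the upper class)."""
    if mean_count < 0:
        raise ValueError("mean count must be non-negative")
    if mean_count < 100:
        return "+"
    if mean_count < 1000:
        return "++"
    return "+++"


def protein_level_category(copies_per_cell: float | None) -> str:
    """Protein abundance category from estimated copies per cell:
    ``-`` not detected, ``+`` < 1e4, ``++`` 1e4–1e5, ``+++`` >= 1e5."""
    if copies_per_cell is None or (
        isinstance(copies_per_cell, float) and np.isnan(copies_per_cell)
    ):
        return "-"
    if copies_per_cell < 0:
        raise ValueError("copies per cell must be non-negative")
    if copies_per_cell < 1e4:
        return "+"
    if copies_per_cell < 1e5:
        return "++"
    return "+++"


def proteomic_ruler(
    intensities: pd.DataFrame,
    molecular_weights: pd.Series,
    histone_flags: pd.Series,
    dna_mass_per_cell: float = 6.5e-12,
) -> pd.Series:
    """Estimate protein copies per cell by the proteomic-ruler principle.

    The summed MS signal of histones is proportional to the DNA mass per
    cell, so ``copies_i = (I_i / MW_i) * dna_mass * N_A / sum_h I_h`` per
    sample, averaged over the samples where the protein is detected.
    ``intensities`` is proteins x samples (NaN/0 = not detected), MW in
    daltons, ``dna_mass_per_cell`` in grams (default 6.5 pg, a diploid
    human genome).
    """
    mw = molecular_weights.reindex(intensities.index).astype(float)
    if (mw <= 0).any() or mw.isna().any():
        raise ValueError("molecular weights must be positive for all proteins")
    hist = histone_flags.reindex(intensities.index).fillna(False).astype(bool)
    inten = intensities.astype(float)
    hist_sum = inten.loc[hist].fillna(0.0).sum(axis=0)
    if not hist.any() or (hist_sum <= 0).all():
        raise ValueError("no histone signal available for the ruler")
    per_sample = inten.div(mw, axis=0).div(hist_sum, axis=1) * (
        dna_mass_per_cell * AVOGADRO
    )
    detected = inten.notna() & (inten > 0)
    per_sample = per_sample.where(detected)
    return per_sample.mean(axis=1, skipna=True).rename("copies_per_cell")


@dataclass
class QpcrMeasurement:
    """Quantification cycles of a target and reference gene in a sample of
    interest and a baseline sample."""

    ct_gene: float
    ct_ref: float
    ct_gene_baseline: float
    ct_ref_baseline: float

    def __post_init__(self) -> None:
        for name in ("ct_gene", "ct_ref", "ct_gene_baseline", "ct_ref_baseline"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")


def ddct(m: QpcrMeasurement) -> float:
    """Relative expression by the delta-delta-Ct method:
    ``2 ** -((Ct_gene - Ct_ref) - (Ct_gene_baseline - Ct_ref_baseline))``."""
    dct = m.ct_gene - m.ct_ref
    dct0 = m.ct_gene_baseline - m.ct_ref_baseline
    return float(2.0 ** (-(dct - dct0)))
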