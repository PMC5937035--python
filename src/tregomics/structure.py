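"""Global views of the polarization: PCA, covariate-association maps,
signature scores projected onto principal components, and a multi-layer
(one layer per treatment group) self-organizing map on a toroidal
hexagonal grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import AbundanceMatrix, SampleDesign

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# PCA and covariate association
# --------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_ratio: pd.Series


def pca(matrix: AbundanceMatrix, n_components: int = 10) -> PCAResult:
    """Centered PCA of samples (genes are features).

    Components are ordered by explained variance; the sign convention
    makes each component's largest-magnitude loading positive.
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    for j in range(n_components):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    var = s**2 / max(X.shape[0] - 1, 1)
    ratio = var / (Xc**2).sum() * max(X.shape[0] - 1, 1)
    names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.columns, columns=names),
        loadings=pd.DataFrame(Vt.T, index=matrix.values.index, columns=names),
        variance_ratio=pd.Series(ratio, index=names),
    )


def variable_association(
    pc_scores: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """R-squared of a separate linear fit of each PC on each covariate.

    Categorical covariates are one-hot encoded (the fit then equals a
    one-way ANOVA eta-squared); constant covariates get R2 = 0 with a
    warning.
    """
    cov = covariates.loc[pc_scores.index]
    out = pd.DataFrame(
        np.nan, index=pc_scores.columns, columns=covariates.columns
    )
    for cname in cov.columns:
        v = cov[cname]
        if v.nunique(dropna=False) <= 1:
            log.warning("covariate %r is constant; R2 set to 0", cname)
            out[cname] = 0.0
            continue
        if pd.api.types.is_numeric_dtype(v):
            X = np.column_stack([np.ones(len(v)), v.to_numpy(dtype=float)])
        else:
            dummies = pd.get_dummies(v, drop_first=True).to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(v)), dummies])
        H = X @ np.linalg.pinv(X)
        for pc in pc_scores.columns:
            y = pc_scores[pc].to_numpy(dtype=float)
            yc = y - y.mean()
            tss = float(yc @ yc)
            if tss == 0:
                out.loc[pc, cname] = 0.0
                continue
            fitted = H @ y
            rss = float(((y - fitted) ** 2).sum())
            out.loc[pc, cname] = max(0.0, 1.0 - rss / tss)
    return out


# --------------------------------------------------------------------------
# signature scores
# --------------------------------------------------------------------------


@dataclass
class Signature:
    name: str
    up: tuple[str, ...]
    dn: tuple[str, ...] = ()


@dataclass
class SignatureScore:
    name: str
    scores: pd.Series  # per sample
    coverage: dict = field(default_factory=dict)
    pc_correlation: pd.DataFrame | None = None  # r and p per PC


def signature_score(z: AbundanceMatrix, signature: Signature) -> SignatureScore:
    """Per-sample score: mean z over the signature's UP genes minus mean z
    over its DN genes (0 when DN is empty); genes absent from the matrix
    are dropped and reported in the coverage dict."""
    idx = z.values.index
    up = [g for g in signature.up if g in idx]
    dn = [g for g in signature.dn if g in idx]
    if not up:
        raise ValueError(f"signature {signature.name!r}: no UP gene in matrix")
    score = z.values.loc[up].mean(axis=0)
    if dn:
        score = score - z.values.loc[dn].mean(axis=0)
    coverage = {
        "up_present": len(up),
        "up_total": len(signature.up),
        "dn_present": len(dn),
        "dn_total": len(signature.dn),
    }
    return SignatureScore(name=signature.name, scores=score, coverage=coverage)


def signature_pc_map(
    scores: list[SignatureScore],
    pc_scores: pd.DataFrame,
    p_cut: float = 1e-6,
    n_pcs: int = 3,
) -> pd.DataFrame:
    """Correlate each signature score with the first PCs and select the
    signatures significant in at least one of them.

    Returns one row per signature with r/p per PC, a ``selected`` flag
    (min p < p_cut) and the (r_PC1, r_PC2) arrow for plotting.
    """
    if pc_scores.shape[1] < n_pcs:
        raise ValueError(f"need at least {n_pcs} principal components")
    pcs = pc_scores.columns[:n_pcs]
    rows = []
    for sc in scores:
        s = sc.scores.loc[pc_scores.index].to_numpy(dtype=float)
        if np.std(s) == 0:
            log.warning("signature %r has zero variance; excluded", sc.name)
            continue
        row: dict = {"signature": sc.name}
        for pc in pcs:
            r, p = scipy.stats.pearsonr(s, pc_scores[pc].to_numpy(dtype=float))
            row[f"r_{pc}"], row[f"p_{pc}"] = r, p
        row["min_p"] = min(row[f"p_{pc}"] for pc in pcs)
        row["selected"] = row["min_p"] < p_cut
        rows.append(row)
    return pd.DataFrame(rows).set_index("signature") if rows else pd.DataFrame()


# --------------------------------------------------------------------------
# multi-layer SOM on a toroidal hexagonal grid
# --------------------------------------------------------------------------


def toroidal_hex_distances(nx: int, ny: int) -> np.ndarray:
    """Pairwise hexagonal grid distances between all cells of an
    ``nx`` x ``ny`` grid with wrap-around (torus), odd-row offset layout."""

    def to_cube(col, row):
        x = col - (row - (row & 1)) // 2
        z = row
        return x, -x - z, z

    coords = [(c, r) for r in range(ny) for c in range(nx)]
    n = len(coords)
    dist = np.zeros((n, n))
    shifts = [(dx * nx, dy * ny) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]
    for i, (c1, r1) in enumerate(coords):
        x1, y1, z1 = to_cube(c1, r1)
        for j, (c2, r2) in enumerate(coords):
            if j < i:
                continue
            best = np.inf
            for sx, sy in shifts:
                x2, y2, z2 = to_cube(c2 + sx, r2 + sy)
                d = max(abs(x1 - x2), abs(y1 - y2), abs(z1 - z2))
                best = min(best, d)
            dist[i, j] = dist[j, i] = best
    return dist


@dataclass
class SuperSOM:
    grid: tuple[int, int]
    layers: list[str]  # group codes, one layer per group
    codebooks: dict[str, np.ndarray]  # layer -> (n_cells, layer_dim)
    layer_columns: dict[str, list[str]]  # layer -> sample ids (column order)
    bmu: pd.Series  # gene -> winning cell index
    quantization_errors: list[float] = field(default_factory=list)


def train_supersom(
    z: AbundanceMatrix,
    design: SampleDesign,
    grid: tuple[int, int] = (20, 20),
    n_epochs: int = 100,
    seed: int = 0,
) -> SuperSOM:
    """Train a batch SOM with one layer per treatment group.

    Genes are the observations; each layer holds a gene's z-scores across
    one group's samples.  Layers are weighted equally (each layer's
    squared distance is normalized by its dimensionality); a unified
    winner cell is found per gene; the Gaussian neighborhood radius decays
    linearly from half the grid diameter to 1 over the epochs.  The grid
    is toroidal hexagonal.  Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    groups = sorted(design.table["group"].unique())
    layer_cols = {
        g: [s for s in design.samples_in(groups=[g]) if s in z.values.columns]
        for g in groups
    }
    layer_cols = {g: c for g, c in layer_cols.items() if c}
    layers = sorted(layer_cols)
    data = {g: z.values[layer_cols[g]].to_numpy(dtype=float) for g in layers}
    n_genes = z.values.shape[0]

    nx, ny = grid
    n_cells = nx * ny
    if n_genes < n_cells:
        while n_genes < nx * ny and min(nx, ny) > 2:
            nx, ny = max(2, nx - 2), max(2, ny - 2)
        log.warning("fewer genes than map cells; grid shrunk to %dx%d", nx, ny)
        n_cells = nx * ny
    dist = toroidal_hex_distances(nx, ny)

    init_idx = rng.choice(n_genes, size=n_cells, replace=False)
    codebooks = {g: data[g][init_idx].copy() for g in layers}
    dim = {g: data[g].shape[1] for g in layers}

    r_start = max(dist.max() / 2.0, 1.0)
    qe_per_epoch: list[float] = []
    bmu = np.zeros(n_genes, dtype=int)
    for epoch in range(n_epochs):
        radius = r_start + (1.0 - r_start) * epoch / max(n_epochs - 1, 1)
        # unified winner: sum of per-layer normalized squared distances
        d2 = np.zeros((n_genes, n_cells))
        for g in layers:
            X, C = data[g], codebooks[g]
            d2 += (
                (X**2).sum(axis=1)[:, None]
                - 2.0 * X @ C.T
                + (C**2).sum(axis=1)[None, :]
            ) / dim[g]
        bmu = np.argmin(d2, axis=1)
        qe_per_epoch.append(float(np.take_along_axis(d2, bmu[:, None], 1).mean()))
        h = np.exp(-(dist[bmu] ** 2) / (2.0 * radius**2))  # genes x cells
        denom = h.sum(axis=0)
        occupied = denom > 1e-12
        for g in layers:
            upd = (h.T @ data[g])[occupied] / denom[occupied, None]
            codebooks[g][occupied] = upd  # empty cells keep their vectors

    return SuperSOM(
        grid=(nx, ny),
        layers=layers,
        codebooks=codebooks,
        layer_columns=layer_cols,
        bmu=pd.Series(bmu, index=z.values.index, name="cell"),
        quantization_errors=qe_per_epoch,
    )


def som_group_time_maps(
    som: SuperSOM, z: AbundanceMatrix, design: SampleDesign
) -> pd.DataFrame:
    """Mean member-gene z per map cell, group and time point — the values
    rendered as the pseudo-colored polarization maps."""
    rows = []
    tab = design.table
    for g in som.layers:
        for tt in sorted(tab.loc[tab["group"] == g, "time"].unique()):
            samples = [
                s
                for s in design.samples_in(groups=[g], times=[tt])
                if s in z.values.columns
            ]
            if not samples:
                continue
            mean_per_gene = z.values[samples].mean(axis=1)
            cell_mean = mean_per_gene.groupby(som.bmu).mean()
            for cell, v in cell_mean.items():
                rows.append(
                    {"group": g, "time": tt, "cell": int(cell), "mean_z": float(v)}
                )
    return pd.DataFrame(rows)


def plot_som_maps(maps: pd.DataFrame, som: SuperSOM, path=None):
    """Render the group x time SOM maps as a panel grid (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(maps["group"].unique())
    times = sorted(maps["time"].unique())
    nx, ny = som.grid
    fig, axes = plt.subplots(
        len(groups), len(times), figsize=(2 * len(times), 2 * len(groups)),
        squeeze=False,
    )
    vmax = maps["mean_z"].abs().max() or 1.0
    for i, g in enumerate(groups):
        for j, tt in enumerate(times):
            ax = axes[i][j]
            img = np.full(nx * ny, np.nan)
            sel = maps[(maps["group"] == g) & (maps["time"] == tt)]
            img[sel["cell"].to_numpy()] = sel["mean_z"].to_numpy()
            ax.imshow(img.reshape(ny, nx), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            ax.set_xticks([])
            ax.set_yticks([])
            if j == 0:
                ax.set_ylabel(g)
            if i == 0:
                ax.set_title(tt)
    fig.tight_layout()
    if path is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
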