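"""Synthetic multi-omics generator with ground truth.

Emulates the statistical structure the analysis pipeline assumes: a
time-course design of several donors x treatment groups x time points,
negative-binomial RNA counts whose baseline log-expression is bimodal
(lowly vs highly expressed genes), planted activation (time) effects,
iTreg-specific group x time effects with a shared core across the iTreg
protocols, transcription-factor hub -> target dependencies with an
early/late regime switch, matched protein log-ratios in concordant /
anti-correlated / delayed / null clusters, and gene-set catalogs
enriched for the planted core.  Everything is deterministic under the
master seed, which spawns one independent substream per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceMatrix,
    CountMatrix,
    ITREG_GROUPS,
    ProteinQuant,
    SampleDesign,
    TIME_HOURS,
)

#: proteomics covers culture from 6 h on, and only the Mock control plus
#: the two protocols carried through the proteome experiment
PROTEOME_GROUPS: tuple[str, ...] = ("G02", "G03", "G05")
PROTEOME_MIN_HOUR: float = 6.0

PROTEIN_CLUSTERS = ("concordant", "anticorrelated", "delayed", "null")


class ConfigError(ValueError):
    pass


def _default_itreg_de() -> dict[str, float]:
    return {"G03": 0.08, "G04": 0.08, "G05": 0.08, "G06": 0.08}


def _default_slopes() -> dict[str, float]:
    return {"concordant": 1.0, "anticorrelated": -1.0, "delayed": 1.0, "null": 0.0}


@dataclass
class SimConfig:
    """Parameters of the generator; defaults mirror the study design
    (3 donors, Mock control plus four iTreg protocols, five post-baseline
    time points) with effect sizes chosen to be realistic for cytokine
    polarization experiments."""

    n_genes: int = 2000
    n_donors: int = 3
    groups: tuple[str, ...] = ("G02", "G03", "G04", "G05", "G06")
    time_points: tuple[float, ...] = (2.0, 6.0, 24.0, 48.0, 144.0)
    frac_leg: float = 0.40
    frac_time_de: float = 0.30
    frac_itreg_de: dict[str, float] = field(default_factory=_default_itreg_de)
    frac_shared_core: float = 0.04
    effect_size_log2: float = 2.0
    nb_dispersion: float = 0.05
    library_size_range: tuple[float, float] = (5e6, 1.5e7)
    frac_tf: float = 0.08
    n_hubs: int = 5
    targets_per_hub: int = 20
    rewired_hub_frac: float = 0.4
    protein_coverage: float = 0.6
    protein_slope_by_cluster: dict[str, float] = field(default_factory=_default_slopes)
    protein_noise_sd: float = 0.25
    n_categories: int = 20
    category_size_range: tuple[int, int] = (50, 150)
    category_enrichment_or: float = 3.0
    seed: int = 0

    # fixed generator constants (documented, not exposed as dials)
    leg_mean_log2fpkm: float = -3.0
    heg_mean_log2fpkm: float = 4.0
    leg_sd: float = 1.2
    heg_sd: float = 1.5
    hub_signal_sd: float = 2.0
    hub_target_coupling: float = 1.0
    donor_sd: float = 0.1

    def validate(self) -> None:
        fracs = {
            "frac_leg": self.frac_leg,
            "frac_time_de": self.frac_time_de,
            "frac_shared_core": self.frac_shared_core,
            "rewired_hub_frac": self.rewired_hub_frac,
            "protein_coverage": self.protein_coverage,
            "frac_tf": self.frac_tf,
            **{f"frac_itreg_de[{g}]": v for g, v in self.frac_itreg_de.items()},
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not self.groups:
            raise ConfigError("empty group list")
        valid = {f"G{i:02d}" for i in range(1, 8)}
        if not set(self.groups) <= valid:
            raise ConfigError(f"groups must be within {sorted(valid)}")
        if list(self.time_points) != sorted(self.time_points):
            raise ConfigError("time_points must be sorted ascending")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.protein_noise_sd < 0:
            raise ConfigError("protein_noise_sd must be non-negative")
        itreg = [g for g in self.groups if g in ITREG_GROUPS]
        if itreg:
            floor = min(self.frac_itreg_de.get(g, 0.0) for g in itreg)
            if self.frac_shared_core > floor + 1e-12:
                raise ConfigError(
                    "frac_shared_core must not exceed the smallest per-group "
                    "iTreg DE fraction"
                )

    def itreg_groups(self) -> list[str]:
        return [g for g in self.groups if g in ITREG_GROUPS]


@dataclass
class SimTruth:
    """Ground-truth labels produced alongside the synthetic data."""

    genes: pd.DataFrame  # is_leg, is_time_de, itreg_de_GXX, is_shared_core,
    #                      is_tf, is_hub, protein_cluster
    hub_edges: pd.DataFrame  # hub, target, regime in {early, late, stable}
    categories: dict[str, list[str]] = field(default_factory=dict)
    planted_categories: list[str] = field(default_factory=list)

    def itreg_de_columns(self) -> list[str]:
        return [c for c in self.genes.columns if c.startswith("itreg_de_")]

    def null_genes(self) -> pd.Index:
        """Genes with no planted time, group, or hub-target effect."""
        flags = self.genes["is_time_de"].copy()
        for c in self.itreg_de_columns():
            flags |= self.genes[c]
        flags |= self.genes["is_hub"]
        in_edges = set(self.hub_edges["target"]) if len(self.hub_edges) else set()
        flags |= self.genes.index.isin(sorted(in_edges))
        return self.genes.index[~flags]


def _time_code(hour: float) -> str:
    for code, h in TIME_HOURS.items():
        if h == hour:
            return code
    raise ConfigError(f"hour {hour} is not one of the canonical time points")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _trajectory(rng: np.random.Generator, n_times: int, amplitude: float) -> np.ndarray:
    """Piecewise-linear log2 offset over the sampled hours: flat up to a
    random knot, then linear to +-amplitude at the last time point."""
    sign = rng.choice([-1.0, 1.0])
    knot = int(rng.integers(0, n_times - 1))
    traj = np.zeros(n_times)
    span = n_times - 1 - knot
    for i in range(knot + 1, n_times):
        traj[i] = sign * amplitude * (i - knot) / span
    return traj


def _group_offset_profile(n_times: int, effect: float, sign: float) -> np.ndarray:
    """Group-specific offset: zero at baseline, half effect at the second
    point, full effect from the third point on (>= effect at >= 2 of the
    post-baseline time points)."""
    prof = np.full(n_times, effect, dtype=float)
    prof[0] = 0.0
    if n_times > 1:
        prof[1] = effect / 2.0
    return sign * prof


def generate_counts(config: SimConfig) -> tuple[CountMatrix, SampleDesign, SimTruth]:
    """Generate NB counts, the sample design, and ground-truth labels."""
    config.validate()
    (
        rng_genes,
        rng_traj,
        rng_group,
        rng_lib,
        rng_hub,
        rng_counts,
        rng_donor,
        rng_prot,
    ) = _spawn(config.seed, 8)

    G = config.n_genes
    genes = pd.Index([f"GENE{i:05d}" for i in range(G)], name="gene_id")
    n_times = len(config.time_points)
    itreg = config.itreg_groups()

    # --- gene annotation ---------------------------------------------------
    lengths = np.round(rng_genes.uniform(500, 5000, size=G)).astype(int)
    is_leg = rng_genes.random(G) < config.frac_leg
    base = np.where(
        is_leg,
        rng_genes.normal(config.leg_mean_log2fpkm, config.leg_sd, size=G),
        rng_genes.normal(config.heg_mean_log2fpkm, config.heg_sd, size=G),
    )
    is_tf = rng_genes.random(G) < config.frac_tf

    # --- planted effects ---------------------------------------------------
    # time-DE among HEGs preferentially (weak genes are undetectable anyway)
    is_time_de = rng_traj.random(G) < config.frac_time_de
    # hubs: TFs with a time effect, needed so they pass the hub filter
    tf_idx = np.flatnonzero(is_tf)
    n_hubs = min(config.n_hubs, len(tf_idx))
    hub_pool = tf_idx[~is_leg[tf_idx]]
    if len(hub_pool) < n_hubs:
        hub_pool = tf_idx
    hub_idx = rng_hub.choice(hub_pool, size=n_hubs, replace=False)
    is_hub = np.zeros(G, dtype=bool)
    is_hub[hub_idx] = True
    is_time_de |= is_hub

    # shared core + per-group iTreg-DE
    # group effects are planted on expressed genes only: a polarization
    # signature is by definition detectable above the LEG floor
    candidates = np.flatnonzero(~is_hub & ~is_leg)
    n_core = int(round(config.frac_shared_core * G))
    core_idx = rng_group.choice(candidates, size=n_core, replace=False)
    is_core = np.zeros(G, dtype=bool)
    is_core[core_idx] = True
    itreg_de = {g: is_core.copy() for g in itreg}
    for g in itreg:
        n_extra = int(round(config.frac_itreg_de.get(g, 0.0) * G)) - n_core
        pool = np.flatnonzero(~is_core & ~is_hub & ~is_leg)
        if n_extra > 0:
            extra = rng_group.choice(pool, size=min(n_extra, len(pool)), replace=False)
            itreg_de[g][extra] = True

    # --- per-gene log2 mean profiles ---------------------------------------
    time_traj = np.zeros((G, n_times))
    for i in np.flatnonzero(is_time_de):
        time_traj[i] = _trajectory(
            rng_traj, n_times, config.effect_size_log2 * rng_traj.uniform(1.0, 1.5)
        )
    core_sign = {i: rng_group.choice([-1.0, 1.0]) for i in core_idx}
    group_offset: dict[str, np.ndarray] = {}
    for g in itreg:
        off = np.zeros((G, n_times))
        for i in np.flatnonzero(itreg_de[g]):
            sign = core_sign.get(i, rng_group.choice([-1.0, 1.0]))
            off[i] = _group_offset_profile(n_times, config.effect_size_log2, sign)
        group_offset[g] = off

    # --- hub -> target wiring ----------------------------------------------
    n_rewired = int(round(config.rewired_hub_frac * n_hubs))
    edge_rows = []
    any_itreg = np.zeros(G, dtype=bool)
    for g in itreg:
        any_itreg |= itreg_de[g]
    # targets carry extra latent variance; keep them clear of the planted
    # group effects so the DE ground truth stays clean
    target_pool = np.flatnonzero(~is_hub & ~is_leg & ~any_itreg)
    used: set[int] = set()
    for k, h in enumerate(hub_idx):
        avail = np.array([t for t in target_pool if t not in used and t != h])
        tgts = rng_hub.choice(
            avail, size=min(config.targets_per_hub, len(avail)), replace=False
        )
        used.update(tgts.tolist())
        rewired = k < n_rewired
        for j, t in enumerate(tgts):
            if rewired:
                regime = "early" if j % 2 == 0 else "late"
            else:
                regime = "stable"
            edge_rows.append((genes[h], genes[t], regime))
    hub_edges = pd.DataFrame(edge_rows, columns=["hub", "target", "regime"])

    # --- assemble the design -----------------------------------------------
    donors = [f"D{d + 1}" for d in range(config.n_donors)]
    rows = []
    for donor in donors:
        for grp in config.groups:
            for hour in config.time_points:
                rows.append(
                    {
                        "sample_id": f"{donor}_{grp}_{_time_code(hour)}",
                        "donor": donor,
                        "group": grp,
                        "time": _time_code(hour),
                        "batch": "B1",
                    }
                )
    design = SampleDesign(pd.DataFrame(rows).set_index("sample_id"))
    S = len(design.table)

    # --- per-sample log2 expression ----------------------------------------
    log2fpkm = np.tile(base[:, None], (1, S))
    hours = design.hours.to_numpy()
    time_index = {h: i for i, h in enumerate(config.time_points)}
    t_of_sample = np.array([time_index[h] for h in hours])
    grp_of_sample = design.table["group"].to_numpy()
    donor_of_sample = design.table["donor"].to_numpy()

    log2fpkm += time_traj[:, t_of_sample]
    for g in itreg:
        mask = grp_of_sample == g
        log2fpkm[:, mask] += group_offset[g][:, t_of_sample[mask]]

    # donor wobble, shared across a donor's samples per gene
    donor_eff = {d: rng_donor.normal(0.0, config.donor_sd, size=G) for d in donors}
    for d in donors:
        log2fpkm[:, donor_of_sample == d] += donor_eff[d][:, None]

    # hub latent signals propagate to targets in the active regime
    hub_of = {genes[h]: h for h in hub_idx}
    latent = {
        gid: rng_hub.normal(0.0, config.hub_signal_sd, size=S) for gid in hub_of
    }
    for gid, h in hub_of.items():
        log2fpkm[h] += latent[gid]
    gene_pos = {gid: i for i, gid in enumerate(genes)}
    early_mask = hours <= PROTEOME_MIN_HOUR
    for _, row in hub_edges.iterrows():
        t = gene_pos[row["target"]]
        z = latent[row["hub"]]
        if row["regime"] == "early":
            active = early_mask
        elif row["regime"] == "late":
            active = ~early_mask
        else:
            active = np.ones(S, dtype=bool)
        log2fpkm[t, active] += config.hub_target_coupling * z[active]

    # --- FPKM -> expected counts -> NB draw --------------------------------
    lib = rng_lib.uniform(*config.library_size_range, size=S)
    mu = (2.0 ** log2fpkm) * (lengths[:, None] / 1e3) * (lib[None, :] / 1e6)
    mu = np.maximum(mu, 1e-8)
    phi = config.nb_dispersion
    n_param = 1.0 / phi
    p_param = n_param / (n_param + mu)
    counts = rng_counts.negative_binomial(n_param, p_param)

    # --- protein cluster labels --------------------------------------------
    covered = rng_prot.random(G) < config.protein_coverage
    cluster = np.array(["none"] * G, dtype=object)
    weights = np.array([0.45, 0.20, 0.20, 0.15])
    cluster[covered] = rng_prot.choice(PROTEIN_CLUSTERS, size=covered.sum(), p=weights)
    # hubs are regulators defined by protein-level evidence: always
    # quantified, tracking their transcript
    cluster[is_hub] = "concordant"

    gene_meta = pd.DataFrame(
        {
            "length_bp": lengths,
            "biotype": np.where(is_leg, "protein_coding", "protein_coding"),
            "symbol": genes,
            "is_tf": is_tf,
        },
        index=genes,
    )
    truth_genes = pd.DataFrame(
        {
            "is_leg": is_leg,
            "is_time_de": is_time_de,
            "is_shared_core": is_core,
            "is_tf": is_tf,
            "is_hub": is_hub,
            "protein_cluster": cluster,
        },
        index=genes,
    )
    for g in itreg:
        truth_genes[f"itreg_de_{g}"] = itreg_de[g]

    matrix = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=design.sample_ids),
        gene_meta=gene_meta,
    )
    truth = SimTruth(genes=truth_genes, hub_edges=hub_edges)
    return matrix, design, truth


def proteome_samples(design: SampleDesign, groups=PROTEOME_GROUPS) -> list[str]:
    """Samples covered by the proteome assay: 6 h onward, selected groups."""
    keep = design.table["group"].isin(groups) & (design.hours >= PROTEOME_MIN_HOUR)
    return list(design.table.index[keep])


def generate_proteome(
    counts: CountMatrix,
    design: SampleDesign,
    truth: SimTruth,
    config: SimConfig,
) -> ProteinQuant:
    """Protein log2R per covered gene: ``slope(cluster) * z(RNA) + noise``.

    The delayed cluster uses the RNA z-profile lagged one time point within
    each donor x group series; the assay covers only the proteomics sample
    subset (6 h onward, Mock + the two protocols with proteome data).
    """
    if config.protein_coverage > 1:
        raise ConfigError("protein_coverage must be <= 1")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(9)[-1])
    samples = proteome_samples(design)
    samples = [s for s in samples if s in counts.sample_ids]
    if not samples:
        raise ConfigError("no proteome samples in the design")
    sub = design.subset(samples)

    covered = truth.genes.index[truth.genes["protein_cluster"] != "none"]
    logc = np.log2(counts.values.loc[covered, samples].to_numpy(dtype=float) + 1.0)
    mu = logc.mean(axis=1, keepdims=True)
    sd = logc.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (logc - mu) / sd

    # lag map: each sample -> same donor/group at the previous time point
    hours_sorted = sorted(sub.hours.unique())
    prev_hour = {h: hours_sorted[max(i - 1, 0)] for i, h in enumerate(hours_sorted)}
    col = {s: j for j, s in enumerate(samples)}
    lag_col = np.arange(len(samples))
    for j, s in enumerate(samples):
        row = sub.table.loc[s]
        h = sub.hours.loc[s]
        prev = sub.table.index[
            (sub.table["donor"] == row["donor"])
            & (sub.table["group"] == row["group"])
            & (sub.hours == prev_hour[h])
        ]
        if len(prev):
            lag_col[j] = col[prev[0]]

    slopes = truth.genes.loc[covered, "protein_cluster"].map(
        config.protein_slope_by_cluster
    )
    delayed = (truth.genes.loc[covered, "protein_cluster"] == "delayed").to_numpy()
    signal = z.copy()
    signal[delayed] = z[delayed][:, lag_col]
    values = slopes.to_numpy()[:, None] * signal
    if config.protein_noise_sd > 0:
        values = values + rng.normal(0.0, config.protein_noise_sd, size=values.shape)

    protein_ids = pd.Index([f"P_{g}" for g in covered], name="protein_id")
    log2r = pd.DataFrame(values, index=protein_ids, columns=samples)
    gene_map = pd.Series(list(covered), index=protein_ids, name="gene_id")
    return ProteinQuant(log2r, gene_map=gene_map)


def _overlap_for_or(m: int, k: int, n: int, target_or: float) -> int:
    """Integer overlap a making the 2x2 odds ratio of an m-sized category
    against a k-sized query in an n-sized background closest to target."""
    best_a, best_err = 0, np.inf
    lo = max(0, m + k - n)
    hi = min(m, k)
    for a in range(lo, hi + 1):
        b, c, d = k - a, m - a, n - k - m + a
        cells = np.array([a, b, c, d], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        o = (cells[0] * cells[3]) / (cells[1] * cells[2])
        err = abs(np.log(o) - np.log(target_or))
        if err < best_err:
            best_a, best_err = a, err
    return best_a


def generate_catalog(truth: SimTruth, config: SimConfig) -> SimTruth:
    """Attach ``n_categories`` gene sets to the truth object.

    Planted categories (a quarter of them, when the target odds ratio
    exceeds 1) oversample shared-core genes so that their expected odds
    ratio against the full background is about ``category_enrichment_or``;
    the rest sample genes uniformly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(10)[-1])
    genes = truth.genes.index
    core = genes[truth.genes["is_shared_core"]]
    non_core = genes[~truth.genes["is_shared_core"]]
    n = len(genes)
    k = len(core)

    n_planted = 0
    if config.category_enrichment_or > 1.0 and k > 0:
        n_planted = max(1, config.n_categories // 4)

    lo, hi = config.category_size_range
    if lo <= 0 or hi < lo:
        raise ConfigError("category sizes must be positive (lo <= hi)")
    categories: dict[str, list[str]] = {}
    planted: list[str] = []
    for c in range(config.n_categories):
        size = int(rng.integers(lo, hi + 1))
        name = f"CAT{c:03d}"
        if c < n_planted:
            a = _overlap_for_or(size, k, n, config.category_enrichment_or)
            members = list(rng.choice(core, size=min(a, k), replace=False)) + list(
                rng.choice(non_core, size=size - min(a, k), replace=False)
            )
            planted.append(name)
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        categories[name] = sorted(members)

    truth.categories = categories
    truth.planted_categories = planted
    return truth


def simulate_all(config: SimConfig | None = None):
    """Convenience wrapper: counts, design, truth (with catalog), proteome."""
    config = config or SimConfig()
    counts, design, truth = generate_counts(config)
    proteome = generate_proteome(counts, design, truth, config)
    truth = generate_catalog(truth, config)
    return counts, design, truth, proteome
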