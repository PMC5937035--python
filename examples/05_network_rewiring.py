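"""Reconstruct hub-centered MI networks and score node rewiring.

Transcription-factor hubs are connected to target genes by a rank-based
mutual-information test inside 200 bootstrap networks pruned by the data
processing inequality; a binomial support test yields the consensus.
Early (0-6 h) and late (1-6 d) networks are compared by the per-node
rewiring score D_n = 1/2 ||w_early - w_late||^2 on unit-sum incident
weights: a hub whose targets switch between windows scores highest.
"""

from tregomics import SimConfig, generate_counts, modlog
from tregomics.network import reconstruct_network, rewiring_scores

config = SimConfig(
    n_genes=200, seed=7, n_hubs=10, targets_per_hub=2, rewired_hub_frac=0.1,
    frac_time_de=0.0, frac_itreg_de={g: 0.0 for g in ("G03", "G04", "G05", "G06")},
    frac_shared_core=0.0, hub_signal_sd=4.0, nb_dispersion=0.005,
    effect_size_log2=0.0,
)
counts, design, truth = generate_counts(config)
stabilized = modlog(counts)
hubs = truth.genes.index[truth.genes["is_hub"]]

early = reconstruct_network(stabilized, hubs, design, window="early",
                            n_bootstraps=200, seed=1)
late = reconstruct_network(stabilized, hubs, design, window="late",
                           n_bootstraps=200, seed=1)
print(f"early network: {len(early.edges)} consensus edges "
      f"({early.edges['support'].mean():.0f} mean bootstrap support)")
print(f"late network:  {len(late.edges)} consensus edges")

dn = rewiring_scores(early, late)
switch = sorted(set(
    truth.hub_edges.loc[truth.hub_edges["regime"] != "stable", "hub"]
))
print("top rewired nodes (D_n, 1.0 = fully switched incidence):")
print(dn.head(5).round(3).to_string())
print(f"planted regime-switch hub(s): {switch} "
      "(expected among the top scores; one-window target nodes score 0.5, "
      "a fully switched hub up to 1.0)")
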