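"""Test the planted core for category enrichment and screen gene pairs.

The shared iTreg core is tested against a catalog of gene sets with a
resampling odds-ratio null and Westfall-Young step-down minP family-wise
error control; then every pair of a few core genes is used as a
two-feature LDA classifier of iTreg versus Mock samples with five-fold
stratified cross-validation in two runs.
"""

from tregomics import SimConfig, modlog, simulate_all
from tregomics.classify import itreg_labels, pairwise_lda_screen, top_classifiers
from tregomics.enrichment import resampling_enrichment

config = SimConfig(n_genes=1000, seed=7)
counts, design, truth, _ = simulate_all(config)

core = list(truth.genes.index[truth.genes["is_shared_core"]])
background = list(truth.genes.index)
res = resampling_enrichment(core, truth.categories, background,
                            n_resample=2000, seed=1)
table = res.table.sort_values("resampling_p")
print("top categories (odds ratio, resampling p, FWER):")
print(table[["odds_ratio", "resampling_p", "fwer"]].head(6).round(4))
hits = set(table.index[table["fwer"] < 0.05])
print(f"FWER < 0.05: {sorted(hits)}  "
      f"(planted: {sorted(truth.planted_categories)})")

labels = itreg_labels(design).dropna()
matrix = modlog(counts).values[labels.index]
reports = pairwise_lda_screen(matrix, labels, core[:6], seed=0)
top, freq = top_classifiers(reports, accuracy_threshold=1.0)
print(f"\n{len(reports)} gene pairs screened; "
      f"{len(top)} separate iTreg from Mock with 100% CV accuracy in both runs")
print("most frequent genes among perfect pairs:")
print(freq.head(3).to_string())
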