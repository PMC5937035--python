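"""Separate expressed from non-expressed genes with a mixture model.

Bulk RNA-seq log2(FPKM) is bimodal: lowly expressed, putatively
non-functional genes (LEGs) versus highly expressed genes (HEGs).  A
two-component Gaussian mixture is fitted per treatment group on per-gene
group means; the threshold t averages the per-group LEG/HEG midpoints,
and a gene counts as expressed when it exceeds t in at least 15 samples.
"""

from tregomics import SimConfig, generate_counts, log2_fpkm
from tregomics.expression import classify_expressed, fit_heg_threshold

counts, design, truth = generate_counts(SimConfig(n_genes=1000, seed=7))
lf = log2_fpkm(counts, pseudo=0.01)

threshold = fit_heg_threshold(lf, design, min_samples=15)
hegs = set(classify_expressed(lf, threshold))

print(f"per-group midpoints: "
      f"{ {g: round(m, 2) for g, m in threshold.midpoints.items()} }")
print(f"threshold t = {threshold.t:.3f} log2(FPKM) "
      "(mean of the group midpoints)")
print(f"{len(hegs)} HEGs of {counts.values.shape[0]} genes")

true_heg = set(truth.genes.index[~truth.genes["is_leg"]])
tp = len(hegs & true_heg)
print(f"agreement with the planted split: precision "
      f"{tp / len(hegs):.3f}, recall {tp / len(true_heg):.3f}")
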