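# tregomics

Time-resolved multi-omics analysis of induced regulatory T cell (iTreg)
differentiation.

Regulatory T cells expressing the transcription factor FOXP3 enforce immune
self-tolerance; understanding which genes drive FOXP3 induction matters for
autoimmunity and cancer immunotherapy. A common experimental design profiles
naive CD4+ T cells activated under a Mock control (group `G02`) and several
Treg-inducing cytokine protocols (`G03`–`G06`, all containing IL-2 and
TGF-β) across a differentiation time course (2 h – 6 d, `T02`–`T06`) in a
few donors, with matched TMT proteomics on a sample subset. `tregomics`
provides the full computational pipeline for such designs, for
bioinformaticians analyzing time-course bulk RNA-seq + proteomics:

- **Expressed-gene thresholding** — per-group two-component Gaussian
  mixtures on log₂(FPKM) separate lowly (LEG) from highly expressed genes
  (HEG); the threshold *t* averages the per-group component midpoints and a
  gene is expressed when log₂(FPKM) > *t* in ≥ 15 samples.
- **Consensus differential expression** — per gene, three models of
  log μ = β⁰ + βᴳxᴳ + βᵀxᵀ + βᴳᵀxᴳxᵀ (NB GLM with discrete time, NB GLM
  with a natural cubic spline of time, stepwise cubic regression); the
  G score counts methods calling a contrast significant and a DEG requires
  G ≥ 2. Proteins get a moderated (empirical-Bayes) linear model with
  binary P scores.
- **Global structure** — PCA with covariate-association R² maps, UP−DN
  signature scores projected on PCs, and a multi-layer self-organizing map
  (toroidal hexagonal grid, one layer per treatment group).
- **RNA:protein integration** — gene-wise pairing, DEG×DEP block partition,
  silhouette-selected hierarchical clustering, per-gene Spearman ρ;
  model-based (Gaussian mixture, BIC, entropy merging) expression clusters
  linked by the permutation-tested association β = Σρᵢ/s.
- **Network reconstruction** — mutual-information edges between TF hubs
  (DEG ∧ DEP ∧ TF) and all expressed genes, 200 bootstraps, data processing
  inequality pruning, binomial consensus; early vs late networks compared by
  the per-node rewiring score Dₙ = ½‖w_early − w_late‖²; the iTreg
  subnetwork is FOXP3 plus all genes DEG in all four protocols.
- **Set enrichment** — odds ratios with resampled nulls and Westfall–Young
  step-down minP FWER control; hypergeometric tests; preranked GSEA.
- **Classification screens** — every pair of candidate genes as a
  shrinkage-regularized LDA classifier of iTreg vs Mock with stratified
  five-fold CV in two runs, plus a bagged-tree out-of-bag
  permutation-importance ranking of all expressed genes.

A bundled synthetic-data generator (`tregomics.simulate`) reproduces the
statistical structure this analysis assumes — bimodal expression,
negative-binomial counts, planted activation and iTreg-specific effects with
a shared core, hub→target dependencies with an early/late regime switch,
matched protein clusters, enriched catalogs — together with ground-truth
labels, so every stage is testable end to end without external data. See
`docs/methods.md` for the models, defaults and limitations.

## Worked example

Scripts under `examples/` exercise one capability each. Thresholding and
consensus DE on a synthetic dataset:

```sh
$ python examples/02_expression_threshold.py
per-group midpoints: {'G02': 4.6, 'G03': 4.16, 'G04': 4.06, 'G05': 3.91, 'G06': 4.15}
threshold t = 4.178 log2(FPKM) (mean of the group midpoints)
599 HEGs of 1000 genes
agreement with the planted split: precision 0.992, recall 0.998
```

The fitted cut (t ≈ 4.2 log₂ FPKM here) sits in the density dip between the
LEG and HEG modes; 599 of 1000 genes clear it in ≥ 15 samples, matching the
planted expressed fraction almost exactly.

```sh
$ python examples/03_consensus_differential_expression.py
DEGs for time:  116 (genes with G >= 2 of 3 methods)
DEGs for  G03:   75 (genes with G >= 2 of 3 methods)
DEGs for  G04:   96 (genes with G >= 2 of 3 methods)
DEGs for  G05:   57 (genes with G >= 2 of 3 methods)
DEGs for  G06:   50 (genes with G >= 2 of 3 methods)
shared across all four iTreg protocols: 22 genes; 15/16 planted core genes found
proteins modeled: 244; DEPs for time: 30, G03: 0, G05: 0 (FDR < 0.05)
(protein group effects are z-compressed by construction, so DEP counts are far below DEG counts, as in the real system)
variance-prior df fitted by empirical Bayes: 3.1
```

The activation (time) effect dominates, each protocol adds a smaller
group-specific response, and the intersection over all four protocols — the
shared iTreg signature — recovers 15 of the 16 planted core genes in this
400-gene run.

A thin CLI chains the stages on TSV/GMT files:

```sh
tregomics simulate --config sim.yaml --outdir data/
tregomics filter --datadir data/ --outdir out/filter
tregomics de --datadir data/ --outdir out/de
tregomics network --datadir data/ --dedir out/de --outdir out/network
tregomics run-all --outdir out/   # the whole pipeline
```

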