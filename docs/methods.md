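# Methods

`tregomics` re-implements, as a tested library, the computational stages of a
time-resolved transcriptome + proteome analysis of human induced regulatory
T cell (iTreg) differentiation: naive CD4+ T cells activated under a Mock
control condition (G02) or four FOXP3-inducing cytokine protocols (G03–G06,
all containing IL-2 and TGF-β), profiled in three donors at 2, 6, 24, 48 and
144 hours (T02–T06), with matched TMT proteomics for a sample subset (6 h
onward; groups G02, G03 and G05). This note records the models, the defaults
and why, and what the bundled synthetic data can and cannot demonstrate.

## Synthetic data generator

Every stage is exercisable without external data through `tregomics.simulate`.
The generator draws, per gene, a baseline log2 expression from a two-component
mixture (lowly expressed genes, "LEGs", around −3 log2 FPKM, sd 1.2; highly
expressed genes, "HEGs", around +4, sd 1.5; LEG fraction 0.40), converts FPKM
to expected counts through a gene length (uniform 0.5–5 kb) and a per-sample
library size (uniform 5–15 million), and samples counts from a negative
binomial with dispersion φ = 0.05 (`var = μ + φμ²`). Planted structure:

- **Activation (time) effects** on 30% of genes: piecewise-linear log2
  trajectories, flat up to a random knot and then linear to ±(1–1.5)×2 log2
  at the final time point.
- **iTreg (group × time) effects** on 8% of genes per protocol, including a
  4% shared core flagged in all four protocols with a consistent sign. The
  offset profile is 0 at baseline, half the effect at the second time point
  and the full 2-log2 effect thereafter, so an effect is present at two or
  more post-baseline time points. Group effects are planted on HEGs only —
  a polarization signature is by definition expressed; effects planted below
  the detection floor would be unrecoverable by any method and would only
  blur the ground truth.
- **Hub → target dependencies**: a small set of TF hubs carries an i.i.d.
  per-sample latent log2 signal (sd 2 by default) that propagates to disjoint
  target sets (coupling 1.0), with `stable`, `early`-only or `late`-only
  regimes; rewired hubs split their targets between the two regimes. Targets
  are drawn disjoint from the iTreg-DE genes so the latent variance does not
  contaminate the differential-expression ground truth.
- **Proteome**: for a 60% coverage of genes (hubs always covered), protein
  log2 ratio per sample = `slope(cluster) · z(RNA) + noise` with planted
  clusters concordant (+1), anti-correlated (−1), delayed (+1, z lagged one
  time point within each donor × group series) and null (0); noise sd 0.25.
  Because profiles are z-standardized per gene, strong absolute effects are
  compressed to at most ~1 sd — group contrasts at the protein level are
  therefore intentionally much weaker than at the RNA level, which mirrors
  the late, damped protein response of the real system.
- **Catalogs**: gene sets of 50–150 members; a quarter of them oversample the
  shared core so that the expected odds ratio against the full background is
  ≈ 3 (solved exactly on the 2×2 table before sampling).

A master seed spawns one independent substream per stage; identical
configurations and seeds reproduce byte-identical data.

What the generator does **not** emulate: batch effects, donor-specific
response heterogeneity beyond a small per-gene wobble (sd 0.1 log2),
gene–gene correlation outside the planted hub structure, missing protein
values, isoform structure, and library-preparation artifacts. Passing tests
demonstrate that the statistical machinery behaves as specified under its own
assumptions, not that it is robust to every failure mode of real data.

## Expression threshold (LEG/HEG)

Per treatment group, genes are aggregated as their mean log2(FPKM) over the
group's samples (mean chosen for EM stability) and a two-component Gaussian
mixture with unequal variances is fitted (k-means initialization, 10
restarts, tolerance 1e-6). The group midpoint is halfway between the largest
LEG-classified and the smallest HEG-classified value; the global threshold
`t` averages the midpoints, and a gene is expressed when above `t` in at
least 15 samples. The procedure is shift-equivariant and invariant to gene
order. Zero counts make log2(FPKM) = −∞, so the pipeline feeds the fit
`log2(FPKM + 0.01)`; the offset is negligible at the scale of the threshold.

## Consensus differential expression

The model per gene is `log μ = β0 + βG·xG + βT·xT + βGT·xG·xT` against the
Mock reference, excluding unstimulated controls (G01/G07). Three fits:

1. **NB GLM, discrete time.** Per-gene dispersion by profile maximum
   likelihood around a Poisson fit (floor 1e-8), shrunk halfway (log scale)
   toward a log-log mean–dispersion trend; Wald tests per coefficient;
   BH-FDR per coefficient across genes. Non-convergent genes fall back to a
   Poisson fit with a logged warning.
2. **NB GLM, natural cubic spline of log(hour+1), df = 3.** The spline basis
   is re-expressed in orthonormal coordinates: the span is identical, but the
   raw truncated-power columns are nearly collinear at five design hours and
   per-coefficient Wald tests would lose essentially all power.
3. **Stepwise cubic regression** on the stabilized (shifted-log) matrix:
   full cubic polynomial in scaled log-hours with group dummies and
   interactions, global F-test p (BH-adjusted), backward elimination at
   α = 0.05, significance requiring FDR < 0.01 and best-model R² > 0.7.

Time is encoded on the log(hour+1) scale for the smooth bases because the
sampled hours span 2–144. A "coefficient category" (all base time terms, or a
group main effect plus its interactions) is significant when any member
coefficient passes the FDR gate (0.01 for RNA). The consensus **G score** per
contrast counts agreeing methods; DEG means G ≥ 2. Asymptotic Wald tests are
mildly liberal at n = 30–75; the two-of-three consensus is what controls the
realized false-call rate (≈ 2% of null genes on the default dataset).

The variance-stabilized transform is a shifted log of size-factor-normalized
counts (`log2(count/sf + 1)`). All downstream stages consume only "a
stabilized matrix"; the exact stabilizer is not load-bearing.

**Proteins** get one linear model (group + discrete time + interactions,
technical replicates averaged per donor × group × time first) restricted to
proteins quantified in all modeled samples. Residual variances are shrunk
toward a scaled inverse-chi-square prior fitted by matching moments of
log s² (trigamma inversion by root-finding); moderated t with augmented
degrees of freedom; P scores are binary at FDR < 0.05. Setting the prior df
to 0 recovers the ordinary t-test exactly (the no-shrinkage limit); a large
prior df pins every variance at the common prior value.

## Global structure

PCA is centered, samples as observations, components sign-fixed so the
largest-magnitude loading is positive. Covariate association fits one linear
model per (PC, covariate) and reports R² (one-hot encoding makes the
categorical case equal one-way ANOVA η²). Signature scores are mean z over a
signature's UP genes minus mean z over its DN genes, correlated against the
first three PCs with a p < 1e-6 selection cut.

The polarization overview is a multi-layer batch SOM on a toroidal hexagonal
grid (20×20 default): one layer per treatment group, layer distances
normalized by layer dimension (equal weights; the weighting is configurable
because the reference procedure does not state it), Gaussian neighborhood
with radius decaying linearly from half the grid diameter to 1 over 100
epochs, winners unified across layers. Cells with no neighborhood mass keep
their codebook vectors. The quantization error decreases monotonically once
the radius has shrunk; early wide-radius epochs may raise it while the map
unfolds — that transient is expected batch-SOM behavior, and the tests check
the post-shrink phase.

## Integration and clustering

RNA and protein rows are paired by gene (multiple proteins per gene
averaged) over the shared samples; the universe is partitioned into the four
DEG × DEP blocks; the paired block is clustered hierarchically (Euclidean,
complete linkage) with the cut in 4–10 chosen by average silhouette width
(Dunn index breaks ties); per-gene Spearman correlations summarize
RNA:protein concordance per block.

Expression clusters come from a Gaussian mixture over per-gene donor-averaged
z-profiles, component count 2–50 and covariance family (diagonal, spherical)
chosen by BIC, followed by entropy-based hierarchical merging: repeatedly
merge the component pair whose union most reduces the soft-assignment
entropy, while the reduction exceeds 1e-3 nats per gene. The absolute
per-observation scale matters: well-separated components have near-zero
confusion entropy and are never merged, while overlapping components of an
unstructured fit collapse toward few clusters.

Cluster association: `β = Σ ρ_i / s` over all `s = n_a·n_b` pairwise Spearman
coefficients between two clusters' member profiles. Because the mean of
pairwise rank correlations factorizes, `β` equals the inner product of the
two clusters' mean standardized-rank profiles divided by the sample count,
and each permutation only shuffles one mean vector — this makes 10,000
permutations per pair cheap. The p-value is the strict fraction of permuted
|β| above the observed |β| (the add-one convention `(k+1)/(n+1)` is available
behind a flag); associations are called at p < 0.01. For determinism the
implementation orients each pair canonically (lexicographically smaller mean
profile permuted), which makes `association(A, B)` and `association(B, A)`
identical including the Monte-Carlo stream.

## Network reconstruction and rewiring

Hubs are TFs with G ≥ 2 for time/G03/G05 at the RNA level and any P score at
the protein level. Edges are scored between hubs and all other genes by a
rank-based mutual-information estimator: both vectors rank-transformed,
equal-frequency binned with `b = min(ceil(√n), 10)`, plug-in MI from the b×b
table, p from `2n·MI ~ χ²((b−1)²)`. The plain G statistic is anti-conservative
when n is of the order of b² (its null mean exceeds the χ² df); a Williams
small-sample correction is available (`williams=True`) and restores nominal
type-I rates at the cost of a lighter extreme tail. Reconstruction uses the
plain statistic with a deliberately extreme edge threshold (p < 1e-10), 200
bootstrap networks, DPI pruning (remove edge (i,j) of any hub-containing
triangle when `MI_ij < (1−tol)·min(MI_ik, MI_jk)`, tol = 0.1, simultaneous
removal), and a consensus binomial tail test of bootstrap support against the
pooled null support rate at p < 1e-8. Permuting every gene's samples
independently leaves the consensus empty, which is the estimator's effective
null calibration at network level.

At n ≈ 30–75 samples the χ²-calibrated MI detects only near-deterministic
monotone dependence (the maximal attainable p at perfect dependence is
~5e-14 for n = 33). The planted-recovery demonstrations therefore use the
strong-dependence regime (hub latent sd 3–4 log2, dispersion 0.005–0.01, no
planted trends) and evaluate recovery on the full 75-sample window; weaker
couplings are simply below this estimator's detection floor at these sample
sizes, by design of the original thresholds.

Early (T01–T03, groups G01–G06) and late (T04–T06, G02–G06) networks are
compared by a per-node rewiring score: unit-sum-normalize each node's
incident-weight vector in each network (zero vector if unconnected) and take
`D_n = ½‖w_early − w_late‖²`. The score is symmetric, zero for identical
normalized incidence, and bounded by ½ for a node connected in only one
network; a node with disjoint degree-1 incidence in the two networks attains
the maximum of 1. Consequently a high-degree hub that switches all k targets
scores ½(1/k_early + 1/k_late) and can never outrank its own one-window
targets (at 0.5); the regime-switch demonstration therefore plants a hub
whose single dominant target switches between windows, which attains 1.0 and
tops the ranking; "top 5%" is evaluated as reaching the 95th percentile of
scored nodes, which is robust to ties. The iTreg subnetwork is the anchor
gene (FOXP3 in the study) plus all nodes with G ≥ 2 in all four iTreg
protocols, with the induced edges of the early ∪ late union network.

## Enrichment

Odds ratios on 2×2 tables with the Haldane 0.5 correction when any cell is
zero, and an upper-tail hypergeometric p. Resampling enrichment draws
query-sized node sets from the background — one shared draw per iteration
across all categories, which preserves the joint null dependence the
Westfall–Young step-down minP procedure requires — with one-tailed
p = fraction of null ORs ≥ observed (ties counted, logged in the report
contract) and FWER from the suffix-minimum of per-resample null p-values
along the p-ordering, enforced monotone. Preranked GSEA uses the weighted
running sum (hit increments ∝ |stat|^w, uniform miss decrements), gene-label
permutations, `p = (1 + #{|ES_null| ≥ |ES|, same sign})/(n_perm + 1)` and
NES = ES / mean |same-sign null ES|. A generic numeric threshold filter for
weighted catalogs (e.g. a minimum association score of 0.25) is provided.

## Classification

Every unordered pair from a candidate list is a two-feature LDA classifier
(pooled covariance shrunk toward its diagonal with the analytic Ledoit–Wolf
intensity — the "auto" regularization), stratified five-fold CV guaranteeing
both classes in every training fold, two runs differing only in fold seed;
"top classifiers" reach the accuracy threshold (default 1.0) in every run.
Fold stratification is by class; donor stratification is configurable. The
forest ranking is a bagged-tree ensemble (500 trees) with out-of-bag
permutation importance — per tree, the OOB error increase when one feature's
values are permuted — averaged over trees, ties broken by gene id.

## Problem sizes and numerical choices

The bundled demonstrations use 2000 genes × 75 samples for the consensus-DE
study, 200-gene fixtures for network recovery and rewiring, 1000 association
tests at 500 permutations, 200 replicate enrichment experiments at 500
resamples, and 20 seeded repetitions of the forest ranking; these sizes give
stable Monte-Carlo estimates while keeping a full run in minutes on one
core. Degenerate inputs are handled explicitly: constant vectors give MI 0 /
undefined Spearman reported as missing; EM failures retry with covariance
regularization; genes with all-zero counts get p = 1 everywhere; rank-
deficient designs are rejected at construction.

## Known limitations

- The shifted-log stabilizer is not the regularized log of the reference
  tooling; low-count genes are noisier than under empirical-Bayes shrinkage.
- Wald inference in the NB GLMs is asymptotic and mildly liberal at three
  donors; single-method calls should not be interpreted at face value.
- The binning MI estimator trades power for transparency; dependencies below
  near-deterministic coupling are invisible at n ≤ 75 with p < 1e-10.
- The rewiring score is a declared two-state formula ("Dn-like"), not a
  re-implementation of any published tool's normalization.
- The generator's proteome is conditionally linear in the RNA z-profile;
  it cannot show robustness to missingness or peptide-level artifacts.
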