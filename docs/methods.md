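# Methods

`krnet` implements a hierarchical multi-omics analysis: heterogeneous
case/control studies of gene expression, miRNA expression and DNA
methylation are each condensed into a layer meta-signature by rank-products
meta-analysis; the three signatures are integrated into genes under
multiple regulatory controls (GMCs); a molecular interaction network built
around the GMCs is scored topologically to nominate key-regulator (KR)
hubs; and the KRs are validated by gene set enrichment and survival
analysis. A seeded synthetic-data generator with planted ground truth
stands in for the public tumor compendia the design targets, so every stage
is verifiable against known truth.

## Rank-products meta-analysis

For one omics layer with studies k = 1..K, each study contributes
fold-change vectors over the shared feature universe (the intersection of
the studies' feature identifiers; features absent from any study are
dropped and logged — intersection avoids imputation). Two fold-change modes
exist:

- **pairwise** (default): every (tumor, normal) sample pair within a study
  yields one log2 fold-change vector. This is the original rank-product
  scheme for unpaired two-class designs. With n tumor and m normal samples
  a study contributes n·m comparison vectors.
- **per-study**: a single fold change per study (difference of class
  means), the cross-study mode of meta-analysis toolkits. The modes
  coincide when each class has one sample.

Within each comparison, features are ranked (average ranks for ties;
descending fold change for the "up" analysis, ascending for "down") and
the rank product is the geometric mean of a feature's ranks:

    RP(g) = ( prod_c r_c(g) )^(1/C)        over all C comparisons.

The pairwise mode is the default because the per-study variant's
sensitivity is intrinsically capped at desk scale: with K = 3 studies and
n = 1000 features, the expected number of null rank products below the
observed value at rank r is E(r) ≈ n·P(∏ of three uniform ranks ≤ (r/n)³),
which already exceeds 0.05·r near r ≈ 30 — so a 5% FDR call can never
recover a 10% planted fraction, however strong the effect. Pooling all
sample pairs concentrates the geometric mean sharply for genuinely
differential features and removes the cap while keeping the permutation
p-values calibrated.

Significance is assessed by class-label permutations: labels are shuffled
independently within each study (class sizes preserved, one seeded stream
per study keyed by study id — outputs are therefore invariant to study
input order), and all RPs recomputed. With E(g) the average per-permutation
count of null RP values (pooled over features) at or below the observed
RP(g):

- `pval(g) = E(g) / n_features` — the per-feature permutation p-value,
  uniform under the null (simulation: 4.8–6.0% of features at p ≤ 0.05
  with zero planted effect);
- `pfp(g) = E(g) / rank(g)` — the percentage-of-false-positives estimate,
  the rank-product convention for FDR. Under a complete null pfp ≈ 1 for
  essentially every feature, so the flagged set is empty — pfp is an FDR
  estimate, not a p-value, and the two are reported side by side.

The pipeline flags features at pfp ≤ 0.05 (default, configurable); no
fold-change filter is applied on top. A feature passing both one-sided
analyses (possible under ties) is resolved to the direction with smaller
pfp, so a feature is significant in at most one direction.

## Integration into GMCs

- **miRNA-regulated genes**: significant genes appearing in the
  target-prediction table as targets of significant miRNAs. miRNA
  identifiers are canonicalized (lowercase, species prefix stripped when
  followed by a mir/let stem); -5p/-3p arms are collapsed only when an
  exact match fails, and the event is logged. No direction constraint.
- **Methylation-regulated genes**: significant genes owning ≥ 1
  significant methylation site under the site→gene map. Direction is
  deliberately ignored for membership; a multi-site gene takes its
  direction from the minimum-pfp site.
- **Functional interaction filter**: Pearson correlation of each candidate
  (miRNA, gene) pair across matched-sample profiles; pairs with
  |R| ≥ 0.8 (default) are kept, R reported signed. Zero-variance profiles
  are skipped with a warning. Lowering the threshold can only grow the
  edge set.
- **GMCs**: genes in both regulated sets that retain ≥ 1 functional miRNA
  edge. The inverse-concordance statistic is the fraction of GMCs whose
  expression and methylation directions oppose.

## Network topology and KR hubs

The global network keeps interactome edges whose two endpoints are both
significant genes and adds the functional miRNA–gene edges; only nodes
incident to a retained edge appear. The CGMC network is the induced
subgraph on the GMCs present plus their first neighbors (edges among
neighbors retained — the module is cohesive, not a union of stars).

Two unweighted topology indices are computed on the CGMC network:

- **stress centrality** — the number of shortest paths (all geodesics of
  all unordered node pairs within a component) on which a node lies as an
  interior vertex, computed with a Brandes-style accumulation
  (δ_s(v) = σ_sv · Σ_w (1 + δ_s(w)/σ_sw) over successors w, summed over
  sources and halved);
- **neighborhood connectivity** — the mean degree of a node's neighbors
  (0 for isolated nodes, logged).

Nodes are ranked on each index (rank 1 = largest, average ranks for ties)
and the AR score is the mean of the two ranks; AR is invariant to monotone
transformations of the indices. Nodes with AR ≤ 10 (default, inclusive at
the boundary) are KR hubs; miRNA nodes are eligible by default and a flag
restricts calls to genes. If the scored network has no more nodes than the
cutoff, every node is returned with a prominent warning.

## KR cluster enrichment

CGMC genes are partitioned around the KR genes by fixed-medoid k-medoids
assignment (Euclidean distance between expression profiles; ties to the
lower-AR medoid). The swap phase of full PAM is disabled by default so the
partition stays centered on the KRs; `allow_swap=True` enables a greedy
swap search for comparison.

Each KR cluster is scored as a gene set by a weighted Kolmogorov–Smirnov
running sum over the list of CGMC genes ranked by the two-sample t
statistic (tumor vs normal; ties broken by gene identifier): hits add
|t|^p / Σ_set |t|^p (p = 1 default), misses subtract 1/(N − set size); ES
is the signed maximum deviation and the leading edge is the set members at
or before the extremum. Null distributions come from phenotype-label
permutations (the ranked list is regenerated per permutation);
NES = ES / mean |same-sign null ES|; the nominal p is the same-sign null
tail fraction; FDR q follows the standard NES-based ratio of null to
observed tail fractions, clipped at 1 and made monotone in |NES| within
each sign. A set is called at nominal p ≤ 0.05 and q ≤ 0.25. Sample order
is canonicalized internally so results do not depend on column
arrangement.

Generic over-representation of a query set against GMT terms uses the
one-sided hypergeometric tail with BH adjustment across terms.

## Survival validation

- **Kaplan–Meier**: S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over distinct event
  times; samples censored exactly at an event time remain at risk at that
  time (standard convention).
- **Log-rank** (2 groups, 1 df): O₁ − E₁ summed over event times with
  variance V_t = d_t (n₁t/n_t)(n₂t/n_t)(n_t − d_t)/(n_t − 1); times with
  n_t = 1 are skipped; χ² = (O₁ − E₁)²/ΣV, p from χ²(1). Implemented
  natively because the at-risk and variance conventions are part of the
  contract, and cross-checked against lifelines in the test suite.
- **SOM grouping**: a 1×2 self-organizing map over samples under the
  Pearson-correlation distance d = 1 − r, initialized from the two
  maximally distant samples, trained online in seeded random order with a
  learning rate decaying linearly 0.5 → 0.01 over n_iter passes. The
  Pearson distance is level-invariant: it groups samples by KR expression
  *shape*, not overall level, so it only separates cohorts that contain
  contrasting KR profiles.
- **Single-KR splits**: groups {expression ≤ cut} vs {> cut} with the cut
  at the median (default) or mean; significance at log-rank p ≤ 0.075
  (the configurable default); the reported direction is the sign of the
  high-expression group's median-survival advantage, falling back to the
  sign of its (E − O) when a median is undefined.

## Synthetic data: what it emulates, and what it does not

Defaults describe a desk-scale compendium: 3 studies per layer, 1000
genes / 150 miRNAs / 1200 CpG sites (~2–3 differential sites per regulated
gene, ~1 primary miRNA regulator per regulated gene), 10 samples per class
per study, 10% planted differential features at mean |log2FC| 2 over unit
residual noise, per-study per-feature batch shifts of SD 0.5, 40 planted
GMCs containing 5 hubs, decoy:true target ratio 3, a matched cohort of 30
samples, a survival cohort of 200 samples with per-KR unit log-hazard and
20% independent censoring. Expression noise is additive Gaussian on the
log2 scale; methylation is the logistic transform of a latent Gaussian
signal, which keeps beta values in [0, 1]. Planted differential CpGs draw
mid-range baselines (logit-scale N(0, 0.75)) because a site saturated near
beta 0 or 1 cannot express a shift — matching the variable sites real
differential-methylation analyses select. GMC methylation direction
opposes the expression direction with probability 0.7, so the
inverse-concordance statistic has a known target.

Matched profiles give each planted miRNA a latent factor; the miRNA and
its primary targets load on it with weight 1 plus residual noise (SD 0.2;
pair |R| ≈ 0.96), with the correlation sign following the planted
directions; all other rows are independent, so decoys fail the |R| ≥ 0.8
filter with probability ≥ 0.95.

The interactome is a Barabási–Albert (m = 3) scale-free background over
all genes with a planted disease module wired on top: non-hub GMCs gain
edges to other planted differential genes, and each hub is rewired to the
other hubs (a rich club) plus the whole module, topping up its degree with
background genes until it exceeds both the 99th percentile and the maximum
of non-hub degrees. The assortative hub wiring is essential, not
cosmetic: neighborhood connectivity is structurally low for the center of
a star (its many low-degree satellites dominate the average), so hubs
whose extra edges land on pendant genes can never reach the top NC ranks —
only hubs whose neighbors are themselves well connected, as in real
interactome cores, are recoverable by the AR score.

Survival times are exponential with log-hazard = hazard_coef × (sum of
per-KR standardized expression) — hazard_coef is the per-unit effect of
each KR. Censoring is an independent Bernoulli(censor_rate) mark; censored
samples report a uniform fraction of their latent event time.

Every generator derives its stream from the single config seed by stable
sub-seeding (seed, generator-id), so stages reproduce independently of
execution order.

What the generator does **not** emulate: probe-level artifacts,
platform-specific normalization residue, correlated noise between layers,
sponge (competing-endogenous) miRNA interactions, CpG-island structure, or
covariate-dependent censoring. Passing tests demonstrate the machinery is
correct at planted truth under these idealizations; they do not certify
performance on real cohort data, where effect heterogeneity
(`effect_heterogeneity_sd`) and annotation noise will reduce recovery.

## Numerical and degenerate-input conventions

- Quantile normalization assigns sorted-column row means by ordinal
  within-column rank, so all columns share the sorted vector exactly and
  the map is idempotent.
- Welch t per feature; zero-variance features with zero mean difference
  get p = 1 and an `untestable` flag; distinct constants get p = 0.
- BH is the multiple-testing adjustment wherever an adjusted p is needed.
- Ties: average ranks in all rank computations; GSEA ranking ties broken
  by gene identifier; PAM ties to the first-listed (lowest-AR) medoid.
- pfp is reported raw and clipped at 1; significance uses the raw value.
- Degenerate stops (empty meta-signature, empty GMC set, no KR at the
  cutoff) abort the pipeline with a machine-readable status and a partial
  manifest; the CLI maps them to exit code 3 (2 for input errors).

## Problem sizes used in the checks

The test-suite and acceptance-script simulations run at the default
generator scale (1000 genes, 3 studies, 10/class) with 100–200 label
permutations, 20 end-to-end replicate seeds, 200 null gene sets at 100
GSEA permutations, and 500 log-rank null replicates — sizes chosen so the
statistics they estimate (sensitivity, realized FDR, calibration rates)
carry standard errors comfortably inside the asserted bands.

## Known limitations

- The per-study fold-change mode is retained for comparability but is
  conservative at small K (see above); the pairwise mode is the default.
- The pfp/pval estimates share one permutation pool across features; at
  very small n_perm the discreteness of E is visible in both.
- The FDR q of the GSEA module follows the standard normalized-score
  procedure, which is known to be approximate for small set collections.
- The SOM is a fixed 1×2 grid; it is a two-cluster splitter, not a general
  SOM implementation.
- The full-PAM swap option uses a greedy search, adequate for the tens of
  genes it is applied to, not optimized for large matrices.
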