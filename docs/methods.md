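# Methods

## Scope and model

`coexdup` implements a duplicate-gene co-expression divergence analysis for a
genome with two WGD-derived subgenomes, as a pipeline of five stages over one
gene universe: expression preprocessing, Z-score network construction,
paralog detection and duplication typing, divergence classification, and
subgenome-level network statistics. A synthetic-data module generates every
input with planted ground truth so each stage can be validated end to end.

The central modelling assumptions are:

* Co-expression is measured as the Pearson correlation of asinh-compressed,
  replicate-averaged TPM profiles across tissues. asinh is used rather than
  log because it is defined at 0 and linear for small values while behaving
  like ln(2x) for large ones, limiting the leverage of very highly expressed
  genes.
* Correlations are made comparable by Fisher's variance-stabilizing
  transform, f = atanh(R), and a single global standardization; an edge is a
  pair whose standardized score exceeds a fixed cutoff. The cutoff is a
  tuning constant (default 2.5), not a formal significance level.
* Regulatory divergence of a duplicate pair is summarized entirely by the
  two shared-neighbor proportions (gene1common, gene2common); all network
  context enters through the neighbor sets.

## Stage-by-stage choices

### Expression preprocessing

* Replicate averaging precedes the expression filter: the filter's "tissues"
  are per-tissue means, not individual libraries. Whether filtering should
  happen before or after averaging is genuinely open; filtering on averages
  is the reading consistent with defining expression per tissue/stage, and
  is fixed here.
* Filter: keep a gene iff (count of tissues with TPM > 0) ≥ 3 OR max tissue
  TPM > 5, both comparisons strict. The loader rejects missing values rather
  than imputing; the atlas contract is a complete matrix.

### Network construction

* Standardization population: all defined unordered off-diagonal pairs among
  the filtered genes, each counted once (upper triangle). Zero-variance
  profiles are flagged undefined and excluded from both the moments and the
  edge list. Moments use the population convention (ddof = 0), so the
  standardized scores have sample sd exactly 1.
* Perfectly correlated pairs: R is clamped to ±(1 − 1e-12) before atanh, so
  duplicated profiles get large finite scores (|f| ≈ 14) instead of being
  dropped.
* Memory contract: the all-pairs matrix is streamed in row blocks
  (`block_size`, default 1024 rows); two passes (moments, then edges) give
  results independent of the block size.
* MCL defaults: inflation 2.0, expansion 2, self-loop weight 1, prune
  threshold 1e-5, convergence when the maximum entry change < 1e-6, at most
  200 iterations, binary adjacency (the thresholded network is clustered,
  not the raw scores). Nodes supported by overlapping attractors are
  assigned to the cluster of their lowest-indexed attractor — a
  deterministic tie-break. Modules with ≥ 10 genes are reported separately
  (`ModuleAssignment.large_modules`).

### Paralog detection and duplication typing

* Global Needleman–Wunsch alignment under BLOSUM62 with affine gaps
  (open 11, extend 1: a gap of length k costs 11 + k), via Biopython's
  `PairwiseAligner`. `X` is scored 0 against everything. Coverage counts
  residue–residue aligned columns over the full protein length; a pair is a
  paralog candidate when coverage > 0.4 for **both** members and the raw
  score ≥ `min_score` (default 50). A raw-score floor replaces a BLAST
  E-value cutoff deliberately: E-values depend on database-size conventions
  external to the alignment itself, and the coverage rule is the
  discriminating filter.
* Duplication types are exhaustive and exclusive: WGD iff the two members
  sit on the homeologous maize1/maize2 copies of one synteny block; tandem
  iff same block and subgenome within `tandem_window` (default 5)
  intervening genes; everything else — including pairs with a non-syntenic
  or unplaced member — is inserted. Unplaced members additionally set an
  `unplaced` flag.

### Divergence classification

* Neighbor sets exclude the duplicate partner before intersection and
  denominators, so a single partner edge cannot inflate the overlap.
* Label order: VI (both isolated); V (exactly one isolated, the other with
  ≥ `min_neighbors` = 10); `excluded` if either side has 1–9 neighbors (or
  one side 0 and the other < 10); otherwise the four distance rules with
  radius 0.1 around (1,1), (0.5,0.5), (1,0)/(0,1), (0,0), else
  `unclassified`. The four regions cannot overlap: the closest centers are
  √0.5 apart, more than twice the radius.
* Enrichment of duplication types within divergence types uses a two-sided
  exact binomial test per cell against the marginal proportion among all
  classified pairs (minimum-likelihood two-sided convention), with
  log₂(observed/expected proportion) and a −inf sentinel for empty cells.
  A binomial matches the observed/expected construction directly.
* Age analysis scales dS by the sample sd (ddof = 1) of dS over WGD pairs;
  groups are compared with a two-sided rank-sum (Mann–Whitney) test because
  dS distributions are strongly right-skewed; zero sd raises.

### Subgenome statistics

* Only genes anchored distinctly to maize1 or maize2 contribute to edge
  partitions; edges touching ambiguous/unlabeled genes are counted as
  dropped, so m1-intra + m2-intra + inter + dropped equals the subset total.
* Pathway tests: pathways need ≥ `min_wgd_pairs` (2) retained WGD pairs and
  ≥ `min_edges` (7) labeled edges. Paired t-tests across pathways compare
  maize1 vs maize2 intra densities, pooled intra vs inter densities, and
  absolute intra vs inter counts. If every paired difference is exactly
  zero, the test reports statistic 0 and p = 1 rather than NaN.
* Genome-wide fractionation runs twice: over genes of retained homeolog
  pairs, and over genes whose homeolog was lost.
* Permutation null: each permutation redraws the same number of edges
  uniformly over the labeled nodes; two-sided p uses mean-centered absolute
  deviation with add-one smoothing, p = (1 + #{|null−mean| ≥ |obs−mean|}) /
  (1 + n_perm), so p is never 0.
* The contingency test is a 1-df Pearson chi-square (no continuity
  correction) on (observed edges, unrealized pairs) × (intra pooled, inter)
  — one concrete reading of "contingency analysis" for edge densities.
* Module enrichment: modules with < `min_labeled` (20) maize1+maize2 genes
  are skipped; per-module 1-df chi-square against the genome-wide
  maize1/maize2 proportions; Bonferroni adjustment by the number of tested
  modules.
* Hub genes: each of `n_perm` (1000) permutations draws a uniform simple
  graph with the observed node and edge counts; the cutoff is the
  (1 − α) nearest-rank (ceiling) quantile of the pooled null degree
  distribution, and hubs have observed degree strictly above it. The pooled
  null reads α as a per-gene threshold; a per-graph maximum-degree null is
  available as `null_stat="max"` for a family-wise reading. Integer degrees
  make the realized per-gene false-positive rate match α only to within the
  discreteness of the degree distribution.

## Synthetic data

### What it emulates

The generator mimics a ~64-tissue atlas with 2–3 replicates per tissue,
planted co-expression modules, duplicate pairs of the three duplication
types with simulated dS, two subgenomes with homeologous blocks and
fractionation, and pathway gene sets (GMT).

* **Expression model.** Profiles are designed on the asinh scale, where
  co-expression is defined, and mapped to TPM by a per-gene affine followed
  by sinh. The downstream asinh transform inverts that mapping up to the
  per-gene affine, so planted correlations survive preprocessing *exactly*;
  with `noise_sd = 0` and `within_module_corr = 1`, same-module genes are
  correlated 1 to machine precision after the transform. Each module has
  one latent tissue profile; a member mixes the latent with gene-private
  variation (`within_module_corr` = the expected member–member correlation);
  replicates add Gaussian noise of sd `noise_sd` on the asinh scale.
* **dS** is simulated per duplication type from normals truncated at 0 by
  resampling (defaults: WGD mean 0.15 / sd 0.05; tandem 0.35 / 0.25;
  inserted 0.50 / 0.20 — the recent WGD youngest and tightest, insertions
  older, tandem spread widest), never computed from sequence.
* **Genome structure.** maize1 genes sit on 25-gene blocks with homeologous
  maize2 copies; each homeolog is lost with probability
  `fractionation_rate`, reconciled to the requested maize2 count; 25% of
  maize1 genes (default) and all surplus maize2 genes are placed at
  non-syntenic positions, providing the pool for inserted duplications.
  Every emitted pathway contains at least two retained WGD pairs.

### The divergence benchmark

Types II and III (and `unclassified`) cannot be realized by module
co-membership alone, so `generate_divergence_benchmark` plants each pair
with designed partner genes in correlation space: the two members are given
correlation 0.6; *common* partners sit near their bisector (designed
correlation ≈ 0.87 to both members); *private* partners sit near one member
(≈ 0.95 to the owner, ≈ 0.57 to the other). Block sizes set the target
overlap proportions: II uses 12 common + 12/12 private (→ 0.5, 0.5); III
uses 13 common + 150 private to one member (→ 1, 0.08); `unclassified` uses
9/21/4 (→ 0.30, 0.69, away from every center). Types I/IV/V/VI come from
module membership and isolated profiles. `within_module_corr` attenuates
every designed correlation, which is the benchmark's noise knob.

Because the edge threshold is defined on the *standardized* score scale, the
correlation level that Z = 2.5 corresponds to depends on the spread of the
whole Fisher-score distribution. A real atlas contains broad constitutive
co-expression blocks that set this spread; the benchmark emulates one as a
"backbone" module of near-identical profiles (pairwise correlation 0.998)
whose size is calibrated, from a census of the designed profiles, so that
the cutoff lands midway (in Fisher space) between the strongest designed
non-edge and the weakest designed edge. This makes designed partner edges
deterministic while leaving finite-sample correlation noise (sd ≈ 1/√T for
T tissues) safely below threshold.

### What the generator does not emulate

Count noise (TPM values are smooth transforms of Gaussians, not
negative-binomial counts), library-size and batch effects, overlapping or
hierarchical modules, correlated fractionation along blocks, and sequence
evolution (no synthetic proteome is produced at scale; paralog detection is
validated on small explicit sequence sets). Passing the planted-recovery
tests therefore shows the statistical machinery is correct and calibrated,
not that real-data performance will match.

## Validation sizes

The acceptance computations use problem sizes chosen to exercise each
property at desk scale: 500 planted pairs (~9,000–10,000 genes, 64 tissues)
for divergence recovery; a 500-gene atlas for standardization moments; 100
random peptide pairs (length ≤ 6), 50 random graphs (≤ 8 nodes) and 10
clique collections for oracle agreement; 200 self-null datasets (50 nodes,
80 edges, 199 permutations) and 100 G(n,m) replicates (300 nodes, 3000
edges) for null calibration; 100 runs × 30 pathways (10+10 genes, edge
densities 0.25/0.25 neutral vs 0.30/0.15 dominant) for dominance power; and
a 2,000-gene, 64-tissue end-to-end run for determinism.

## Known limitations

* All-vs-all paralog detection is quadratic in the proteome and intended
  for the few-thousand-protein scale, not a full 40k-gene proteome.
* MCL is run on binary adjacency; weighted variants and other inflation
  values are exposed but unexplored.
* The Z-cutoff sweep {1.5, 2.0, 2.5, 3.0} is exposed as configuration; no
  automatic cutoff selection is implemented.
* The per-gene hub threshold and the contingency-table layout are recorded
  interpretations of analyses whose exact constructions admit alternatives;
  both alternatives are one flag or one function away.
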