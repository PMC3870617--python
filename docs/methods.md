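# Methods

## Study design being modeled

The pipeline targets a small-sample serum miRNA microarray design: three
disease subgroups of 3 patients each (TCM syndromes LGDHS, LDSDS, LKYDS of
hepatocellular carcinoma) against 7 healthy controls, each compared
separately to the controls, followed by target prediction, network
construction and gene-set enrichment per comparison, and cross-comparison
overlap analysis. Because no raw arrays from such a study are available to
ship, all validation runs on simulated inputs with planted truth (below).

## Normalization

Raw intensities are log2-transformed (configurable pseudocount, default 0
since the simulator emits strictly positive values). Two normalizations are
provided as independent switches, because their order and assignment is an
analysis choice rather than a fixed fact:

* per-sample z-score (mean 0, sample variance 1, n−1 denominator) — used for
  clustering and classification, where only profile shape matters;
* per-patient median centering (median exactly 0 per column) — applied to
  the matrix used for differential testing.

Fold changes are always computed on the log2 (pre-z-score) matrix: a fold
change on standardized data would be meaningless. Both transformations
preserve within-column rank order, which the tests assert.

## Random-variance-model moderated t-test

With 3-vs-7 samples a per-miRNA variance estimate has 8 degrees of freedom
and ordinary t-tests are erratic. The RVM assumes per-miRNA precision
1/σ² ~ Gamma(shape a, scale b), equivalently σ² inverse-gamma; the pooled
sample variance then satisfies s²·a·b ~ F(f, 2a) with f = n₁+n₂−2. The
hyperparameters are fitted once per comparison by maximizing the exact
F-marginal log-likelihood (Nelder-Mead on log-parameters from an
inverse-gamma moment start; the fit is audited in tests against a 50×50
grid search and recovers (a, b) within a few percent at 5000 variances).
Each miRNA's test then uses

σ̃² = (f·s² + 2/b̂) / (f + 2â),  df = f + 2â,

so the prior contributes 2â pseudo-degrees of freedom and the statistic
interpolates between the per-miRNA and the prior variance. Limits behave
correctly: as a→∞ with 1/(ab) pinned, the statistic reduces to the pooled t
with the prior-mean variance; as f→∞, σ̃²/s² → 1. Zero-variance miRNAs stay
testable through the prior (warned). If every variance is identical the
prior is degenerate and the fit refuses with a pointer to the ordinary
t-test; a non-converged optimization falls back to the moment start with
`converged=False`.

Significance is the conjunction |log2FC| > log2(1.5) AND two-sided P < 0.05
on the moderated t. No multiple-testing correction is applied at this stage
(an optional BH switch exists, off by default); FDR control enters in
enrichment. Two-sided p-values are used; a one-sided reading of the
threshold is not exposed.

## Clustering

Distances are 1 − centered Pearson correlation (range [0, 2]); linkage is
unweighted average (UPGMA), implemented directly so that ties at equal
candidate heights break toward the pair containing the lexicographically
smallest leaf label, making leaf order — and the exported heatmap row order
and Newick tree — platform-independent. The implementation agrees with
scipy's average linkage and with a direct mean-cross-distance recomputation
to 1e-9 on random matrices. Branch lengths in the Newick export are half
the merge-height increments (ultrametric convention).

## SVM binary classification tree

The class hierarchy over the syndrome groups is found by recursive binary
partition: at each node every bipartition of the class set is scored by
10-fold, 10-repeat stratified cross-validation of a linear SVM (C = 1;
kernel and C configurable — unstated in the source analysis, linear/C=1 is
the standard p ≫ n default) and the best split wins. Feature selection
(ordinary two-sample t-test, α = 0.01) is re-run inside every training
fold, so node scores carry no selection leakage; on null data the score
calibrates to 50% (asserted over 50 seeds). When a fold's filter selects
nothing, that fold falls back to the single smallest-p feature so chance
performance remains measurable; the public `select_features` API instead
raises, advising a larger α. Fold counts degrade to the smallest class size
(leave-one-out at size 1, warned). Because 3-sample classes make k-fold CV
coarse, a .632 bootstrap accuracy (0.368·resubstitution + 0.632·out-of-bag,
30 resamples) is reported alongside the CV score whenever any class has
fewer than 2×folds samples; both estimators are emitted since which one a
given published "score" denotes is generally ambiguous. Scores are reported
both at full precision and rounded to integer percent. All randomness is
derived from one seed via per-bipartition SeedSequence keys, making scores
invariant to sample order.

## Target-prediction consensus

Data A is the union over all unordered pairs of the 9 binary programs of
their pairwise intersections. This is provably the set of genes predicted
by at least two programs, and the test suite enforces that equivalence
against an independent vote-counting oracle on random ensembles. (Reading
the rule as a *single* random pair would make the output irreproducible;
the exhaustive-pair reading is the only deterministic interpretation.)
Data B keeps genes whose score in the score-valued program strictly exceeds
60 — 60 itself is excluded. The consensus is Data A ∩ Data B per miRNA.
Experimentally validated interactions bypass the filter and are merged into
the final edge set flagged `validated` (`both` when also in the consensus),
since both evidence sources feed the network without a published merge
rule. A per-program significance screen is surfaced as a documented no-op
hook: standard prediction exports carry no per-program p-values to test.

## Networks

Per comparison, a bipartite graph over the significant miRNAs and their
final target sets. miRNA nodes carry weight |log2FC| and a direction; gene
nodes carry weight = degree. Invariants checked on every construction:
strict bipartiteness, gene weight equals degree, and the degree-sum
identity (both sides sum to the edge count).

* **Hubs**: nodes with degree ≥ 5 in the parent network (the threshold is a
  parameter), kept together with their incident edges — so a hub's
  neighbors remain as endpoints. Under this reading hub extraction is
  idempotent, which the tests assert.
* **Up-expression subnetwork**: the up-regulated miRNAs and their targets
  (read as repressed/down-regulated genes); the up-fraction is reported as
  a percentage with one decimal.
* **Comparison**: shared miRNA/up-miRNA sets by id intersection; Spearman
  rank correlation (mid-ranks) of node weights over shared nodes with a
  two-sided permutation p (default 10,000 shuffles of one network's
  weights, add-one estimator, seeded); "deregulated nodes" are the top-20
  shared nodes by absolute rank change (k configurable — no published
  cutoff exists). Fewer than 3 shared nodes: overlap counts are returned
  and the rank test is marked not computable.

## Enrichment

Exact hypergeometric upper tail P[X ≥ k] for the query (targets of
up-regulated miRNAs) against each set of a GMT collection — verified to
1e-12 against one-sided Fisher exact tests — followed by Benjamini-Hochberg
adjustment (statsmodels; verified against a naive O(m²) step-up oracle).
Retention requires overlap k ≥ 5 AND raw P < 0.05 AND adjusted P < 0.05;
the minimum-overlap filter runs before the FDR ranking by default (sets
failing it carry no adjusted p), configurable. The universe defaults to the
genes appearing in the prediction ensemble rather than a whole genome,
because a prediction-restricted background is the defensible null for
target lists; it is overridable. The EASE-style conservative variant (k−1
in the tail) is not the default and is not currently exposed.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions:

* **Expression**: baselines Uniform(6, 12) log2 units (typical array
  intensities); per-miRNA Gaussian noise with variance from the same
  inverse-gamma law the RVM assumes (defaults a = 3, b = 1, i.e. prior mean
  variance 0.5 on the log2 scale — a realistic serum-array noise level),
  chosen deliberately so that RVM calibration tests are meaningful. Default
  design: 7 Normal + 3 LGDHS + 3 LDSDS + 3 LKYDS samples; 40 planted DE
  miRNAs per syndrome group (drawn independently per group, so groups can
  share DE miRNAs as real syndromes do), shifted ±2 log2 units, half up and
  half down.
* **Predictions**: each miRNA gets 8 true targets. A true pair becomes
  consensus-recoverable (two guaranteed binary hits, extra hits at 0.3,
  score Uniform(61, 100)) with probability `program_agreement` (default
  0.9); otherwise, and for an equal number of decoy pairs, the construction
  guarantees at least one consensus condition fails (≤1 binary hit and/or
  score Uniform(0, 60)), exercising the >60 boundary from both sides. A 5%
  sample of true pairs forms the validated table.
* **Gene sets**: 50 sets of 20–80 genes; planted-enriched sets draw 60% of
  members from the targets of planted up-regulated miRNAs (overlap odds
  ratio well above 10 at these sizes); all sets have ≥5 members so the
  minimum-overlap filter is exercisable.

What the generator does **not** emulate: array-probe chemistry, background
correction, intensity-dependent (heteroscedastic-in-mean) noise, serum
hemolysis artifacts, correlated miRNA co-expression, or biologically
structured target networks. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated model, not
robustness to those real-data pathologies.

## Pipeline and reproducibility

`run_all` sequences the stages per comparison and writes a manifest with a
config snapshot, the seed, the package version and sha256 hashes of every
output file; re-running with the same config and seed reproduces the hash
block exactly (timestamps are recorded but excluded from the comparison).
One global seed fans out to per-stage seeds through a fixed SeedSequence
derivation, so stages are individually reproducible. A missing gene-set
file skips enrichment with a warning; any other failure aborts with the
stage named, retaining partial outputs.

Default problem sizes (400 miRNAs, 2000 genes, 3+1 groups) keep a full run
and its re-run in seconds on one CPU while leaving all statistical checks
well-powered; the acceptance script's Monte-Carlo sizes (2000 null miRNAs,
5000 variances, 20–50 seeds per calibration) were chosen the same way.

## Known limitations

* The RVM fit assumes a common f across miRNAs (true for complete
  matrices; missing values are not handled).
* The exhaustive bipartition search in the classification tree is limited
  to 6 classes; the intended scale is 3–4.
* Enrichment treats gene sets as flat; no GO-graph topology weighting.
* The permutation rank-similarity test permutes one network's weights,
  which tests exchangeability of weights given the shared node set, not
  network topology.
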