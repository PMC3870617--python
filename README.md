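# syndromirnet

Serum-miRNA expression analysis for comparing disease subgroups against
controls, built around the study design used for traditional-Chinese-medicine
(TCM) syndrome differentiation in hepatocellular carcinoma (HCC): three small
syndrome groups (LGDHS, LDSDS, LKYDS; 3 patients each) versus 7 healthy
controls, profiled on a miRNA microarray.

The package is aimed at computational biologists who need the complete chain
from a log2 expression matrix to compared miRNA-target networks:

1. **Normalization** — per-sample z-scoring and per-patient median centering
   of log2 intensities.
2. **Differential expression** — the random-variance-model (RVM) moderated
   t-test. Per-miRNA precision is modeled as 1/σ² ~ Γ(a, b), so the pooled
   sample variance s² with f degrees of freedom satisfies s²·a·b ~ F(f, 2a).
   After fitting (a, b) by maximum likelihood across all miRNAs, each test
   uses the shrunken variance σ̃² = (f·s² + 2/b̂)/(f + 2â) with f + 2â
   degrees of freedom. A miRNA is significant when fold change > 1.5
   (|log2FC| > log2 1.5) **and** P < 0.05.
3. **Clustering & classification** — UPGMA with the 1 − Pearson metric and a
   deterministic lexicographic tie-break; an SVM binary classification tree
   whose node scores are repeated-CV percent-correct with in-fold feature
   selection (univariate t-test at P = 0.01), plus a .632 bootstrap estimate
   for very small classes.
4. **Target consensus** — Data A (genes predicted by ≥2 of 9 binary-hit
   programs, computed as the union of all pairwise program intersections)
   ∩ Data B (genes scoring >60 in the score-valued program), with validated
   TarBase-style interactions merged in and flagged.
5. **Networks** — bipartite miRNA-target graphs with miRNA weight = |log2FC|
   and gene weight = degree; hub subnetworks (degree ≥ 5), up-expression
   subnetworks with their up-miRNA percentage, and cross-network comparison
   by node overlap and Spearman rank similarity with a permutation p.
6. **Enrichment** — exact hypergeometric over-representation of the
   up-subnetwork's target genes against GMT collections, Benjamini-Hochberg
   FDR, retained iff overlap ≥ 5, P < 0.05 and FDR-adjusted P < 0.05, plus
   retained-term overlap counts between syndromes.

Because the original serum arrays are not publicly deposited, the package
ships a first-class synthetic-data generator (`syndromirnet.simulate`) that
emulates all four inputs — expression matrix, prediction tables, validated
interactions, gene sets — with planted, recoverable ground truth; every
stage is validated against that truth or an independent oracle.

## Worked example

```bash
python examples/01_simulate_and_differential.py
```

prints, for the default design (400 miRNAs, 16 samples, 40 planted DE
miRNAs per group at |log2FC| = 2):

```
matrix: 400 miRNAs x 16 samples
LGDHS vs Normal: 57 significant miRNAs (38/40 planted recovered, 19 false positives)
LDSDS vs Normal: 47 significant miRNAs (38/40 planted recovered, 9 false positives)
LKYDS vs Normal: 61 significant miRNAs (40/40 planted recovered, 21 false positives)
```

i.e. the moderated test recovers ≥95% of planted signals at n = 3 vs 7
while the FC-and-P conjunction keeps the false-positive rate near its
nominal ~5%. Continuing with `examples/02_cluster_and_classify.py`:

```
node 1: LDSDS vs LGDHS+LKYDS, score = 100 (bootstrap 97.9)
node 2: LGDHS vs LKYDS, score = 100 (bootstrap 100.0)
```

the binary tree separates the (well-separated synthetic) syndrome groups
with perfect cross-validated node scores. The remaining examples cover
consensus/network construction, enrichment with cross-syndrome comparison,
and the end-to-end pipeline with its reproducibility manifest.

A thin CLI mirrors the library:

```bash
syndromirnet simulate --out data/ --seed 7
syndromirnet de --matrix data/expression.tsv --groups data/groups.tsv \
    --case LGDHS --out de.tsv
syndromirnet run --config pipeline.yaml --out results/
```

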