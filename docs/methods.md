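# Methods

## Problem and model

A case is a patient with a monogenic syndrome: a set of HPO terms, an
optional per-syndrome facial-gestalt similarity vector, and (for the
benchmark) a known causal gene and the CADD-PHRED score of its causal
variant. For each case the pipeline builds a table with one row per
candidate gene from the exome and five score columns — variant
deleteriousness (`cadd`), gestalt similarity mapped to genes
(`gestalt`), and three HPO-based semantic similarities
(`feature_match`, `phenomizer`, `boqa`) mapped from diseases to genes.
A linear soft-margin SVM trained on pooled rows (causal gene = positive
class) yields the decision function f(x) = w·x̃ + b; this signed
margin is the PEDIA score used to order the genes of a case. The
geometric distance (w·x̃ + b)/‖w‖ would give the same order, so the
unnormalized margin is used.

Assumptions worth stating: rows are treated as i.i.d. across cases
(gene identity is not a feature, so the model cannot memorize genes);
all five scores are "larger is more causal"; missing phenotype scores
mean "no similarity", not "unknown".

## Semantic similarity scores

* **Information content.** ic(t) = −ln(n_t/N) with n_t the number of
  catalog diseases whose annotation closure (ancestor propagation over
  all is_a paths, multiple inheritance included) contains t, N the
  catalog size. ic(root) = 0. Terms reached by no disease get
  max-catalog IC + ln 2: strictly more informative than anything
  observed, which keeps parent→child monotonicity. Natural-log units
  throughout; the downstream classifier standardizes features, so the
  base cancels.
* **Phenomizer-style score.** Symmetric Resnik best-match-average:
  mean over query terms of the best pairwise Resnik similarity
  (max IC over common ancestors) against the disease annotation,
  averaged with the reverse direction. The original tool's
  significance-by-sampling step is deliberately not reproduced; the raw
  similarity feeds the classifier.
* **BOQA-style score.** Exact enumeration of the noisy-observation
  likelihood α^|Q\A| (1−α)^|T\(Q∪A)| β^|A\Q| (1−β)^|A∩Q| over the term
  universe T, with defaults α = 0.001 (false-positive term rate),
  β = 0.1 (false-negative rate) and a uniform disease prior, computed
  in log space and normalized to a posterior. No sampling
  approximations are needed at the catalog sizes used here.
* **Feature match.** The commercial feature-matching algorithm is
  unpublished, so the column is a closure-Jaccard overlap
  |closure(Q) ∩ closure(A)| / |closure(Q) ∪ closure(A)|. The scorer is
  a pluggable callable: externally exported scores can replace it
  without touching the pipeline. The pipeline only requires a monotone
  clinical-feature similarity in this column.

## Variant handling

Rare-disease filtering is reduced to three parameterized predicates —
population allele frequency ≤ 0.01, consequence class in a configurable
protein-altering set, optional deleteriousness floor — because
genotype/inheritance logic is out of scope: per gene only the maximum
deleteriousness among surviving variants is kept, regardless of
genotype, a sensitivity-first heuristic that also serves compound
heterozygotes whose second hit scores low. Missing allele-frequency
annotations count as 0 (assume rare). Multi-allelic VCF sites are split
per ALT before filtering; coordinates stay 1-based.

The spike-in benchmark inserts the causal variant's score into a
background exome's gene→max-score map with a max rule, so a spike-in
never lowers a score and changes at most one entry.

## Gene mapping

Syndrome-level scores (gestalt and the three semantic scores) map to
genes through morbidmap/mim2gene-dialect tables; a gene linked to
several scored syndromes takes the maximum. Phenotype labels carrying a
six-digit MIM normalize to `OMIM:NNNNNN`. Genes never scored by the
mapping are filled with 0 at table assembly — distinguishable in the
intermediate maps (absent vs 0), collapsed only at the classifier
boundary.

## Classifier details

* **Standardization.** Per-feature location/scale fitted on training
  rows only. Raw CADD (~0–40) would otherwise dominate posterior-scale
  columns (~0–1).
* **Class imbalance.** One positive per table of dozens-to-thousands of
  rows; handled by inverse-frequency (`balanced`) class weights on the
  loss. No subsampling, so training is deterministic.
* **C parameterization.** The liblinear primal squared-hinge solver is
  used (deterministic, no RNG). Its data term is a sum, so C is divided
  by the number of training rows internally: C is specified on a
  mean-loss scale, which makes the fit invariant to duplicating the
  training set and keeps C comparable across cohort sizes. The grid is
  all integer powers of two in [2⁻⁶, 2¹²]; granularity beyond the
  endpoints is a declared choice.
* **C selection.** Internal k-fold (default 5) cross-validation over
  *cases*; the C with the highest mean top-1 accuracy wins, ties to the
  smallest C. One scaler per internal fold is shared across the grid
  (it does not depend on C).
* **Ranking.** Genes sorted by decreasing PEDIA score; exact ties break
  lexicographically by gene symbol, so ranks are a deterministic
  permutation 1..N.
* **Weight contributions.** |w_i| / Σ|w_j| on the standardized scale,
  reported as variant (cadd), feature-based (sum of the three HPO
  columns) and gestalt shares.

## Evaluation

Gene-disjoint folds: cases grouped by causal gene; groups shuffled
(seeded), then assigned largest-first to the least-loaded fold. The
balancing objective is case count per fold; only the disjointness
constraint is hard. Top-k accuracy is the per-case fraction with causal
rank ≤ k; the rank-sensitivity curve is top-r for r = 1..max_rank.
Ablations remove inactive columns from the feature vector (the model
dimension shrinks) rather than zero-filling, so the CADD-only combo
reduces exactly to sorting by CADD. All combos in a grid share one fold
assignment and seed.

The transfer experiment emulates adding molecular data to photo-only
cases: each test case borrows the CADD and feature columns of a
uniformly sampled same-diagnosis donor, keeps its own gestalt vector,
and is ranked by a model trained on the cohort minus (a) the donor and
(b) any case with the test case's (causal gene, causal-variant score)
pair — the stand-in for "same pathogenic variant", which is not
otherwise identifiable from the case record. Because a same-diagnosis
donor may carry a different disease gene (heterogeneity), the test
case's causal-variant score is spiked into the borrowed CADD column.
Means and SDs are reported over repeats; the SD is exactly 0 for a
single repeat or identical repeats.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not any real data distribution:

* **Ontology**: `n_terms` (default 60) in a rooted DAG; parents capped
  at `dag_branching` children where possible; second parents with
  probability `multi_parent_prob` (0.15).
* **Catalog**: `n_diseases` (20) × `terms_per_disease` (6) annotations;
  `genes_per_disease` (2) genes drawn from a pool ~15% smaller than the
  slot count so some genes serve several syndromes.
* **Queries**: per-term dropout at 0.2 (one term always kept), plus
  Binomial(|annotation|, 0.1) unrelated noise terms.
* **Gestalt**: Exponential(scale 0.1) baseline per syndrome, +0.5
  (`gestalt_signal`) on the true syndrome.
* **Exomes**: per-ethnicity candidate counts (EUR/EAS 60, AFR 90 —
  more variants survive frequency filters in under-represented
  populations while the score distribution stays comparable);
  background scores Beta(2,5)·40 (right-skewed), causal scores
  N(28, 4) truncated at 0. Plausible CADD-PHRED shapes chosen once;
  they are config, not claims about real exomes.
* **Determinism**: one seeded RNG stream per purpose and per case, so
  enlarging a cohort leaves earlier cases bit-identical.

What passing on these cohorts does **not** show: performance on real
facial-analysis score distributions, real allele spectra, curated-HPO
query quality, or OMIM-scale catalogs. The generator's signal knobs are
the study conditions for the package's benchmarks; headline accuracies
from real cohorts of this design are not reproducible here and are not
asserted.

## Benchmark problem sizes

The shipped benchmark runs use 200-case / 20-disease cohorts with
tenfold gene-disjoint CV (seed-paired over 20 seeds for the
signal-recovery comparison), 1000 cases for the null calibration, and
20 photo-only cases × 10 repeats for the transfer experiment — sizes at
which every result in the test suite and acceptance script reproduces
from scratch in minutes on one CPU.

## Known limitations

* The feature-match stand-in is a Jaccard overlap, not the proprietary
  algorithm; only its monotonicity matters downstream.
* No genotype or inheritance-mode reasoning; the per-gene max heuristic
  discards zygosity entirely.
* No phenotypic-series expansion in the OMIM mapping; only explicit
  syndrome→gene rows are used.
* Squared hinge (primal liblinear) rather than the classical hinge;
  with standardized features and the C grid spanning 2⁻⁶–2¹² the
  selected models are indistinguishable in ranking behaviour, and the
  primal solver is exactly deterministic.
* BOQA uses exact enumeration with a uniform prior; informative priors
  are accepted but nothing estimates them.
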