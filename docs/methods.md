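# Methods

## Problem setting

`funcfly` predicts Gene Ontology (GO) term annotations for *Drosophila
melanogaster* proteins by combining two kinds of evidence:

* **sequence-derived features** (a precomputed numeric matrix, canonically
  258 columns — amino-acid composition, disorder, transmembrane segments and
  similar descriptors; recomputing them from raw sequence is out of scope),
  and
* **temporal transcription expression features** derived from a 30-point
  developmental RNA-seq time course spanning the fly life cycle: embryo
  (T1–T12), larva (T13–T18), pupa (T19–T24) and adult (T25–T30).

Each GO term is treated as an independent binary classification problem over
a reference protein set; model interpretation then links biological-process
terms to the developmental stages in which their expression signal lives.

## Expression features

For each gene with transcripts indexed by isoform, three 30-dimensional
feature families are built per time-point *t*:

* **Num**: the number of *differently expressed* transcripts at *t*,
  implemented as the number of equivalence classes of the transcript
  expression values, where values chained within an absolute `tolerance`
  (default 0) of each other fall into one class. With the default this is
  the count of distinct values, so a single-transcript gene scores 1
  everywhere and a gene with three everywhere-distinct isoform profiles
  scores 3 everywhere. "Differently expressed" has no unique formal reading;
  the distinct-values interpretation is recorded as an assumption and an
  alternative — the count of transcripts expressed above `tolerance` — is
  available via `num_mode="expressed"`.
* **Ave**: the arithmetic mean expression over the gene's transcripts.
* **Main**: the profile of the gene's *main transcript*, defined as the
  isoform with the longest protein sequence; ties are broken by the larger
  total expression summed over the 30 time-points (a permutation-invariant
  reading of "maximum expression", since no single time-point is
  distinguished), then by lexicographically smallest transcript id so the
  rule is total and deterministic.

Proteins inherit their gene's features; a protein mapping to more than one
gene is rejected rather than merged. Feature groups compose in the fixed
order Seq, Num, Ave, Main, giving 258 + 3×30 = 348 columns for the full
combination. Expression values are consumed as provided (no normalisation).

## Per-term datasets

Annotations (GAF 2.x; `NOT`-qualified rows always dropped, evidence-code
exclusion configurable and empty by default) are closed under the true-path
rule: a protein annotated to a term is annotated to every ancestor reachable
via `is_a`/`part_of` within the term's namespace. Non-root terms with at
least `min_positives` (default 100) annotated proteins become prediction
targets. For each term, the annotated proteins present in the feature matrix
are positives and every other matrix protein is a negative — the source data
describe only annotated/non-annotated classes, so no sibling-based negative
exclusion is applied. The protein set is split 7:3 into train and test,
stratified per class with a per-class train size of round(0.7·n) (half-up
rounding, so the documented 20 pos/80 neg example yields 14+56 train and
6+24 test); stratification guarantees both classes appear on both sides.

## Classifier bank and Opt-Classifier selection

Four candidate algorithms are trained per term: Random Forests (500 Gini
trees, sqrt-feature subsampling), AdaBoost (200 depth-1 learners), k-nearest
neighbours (k = 5, Euclidean) and linear discriminant analysis (no
shrinkage). Hyperparameters are fixed, widely used defaults — only the
prior sequence-only SVM system was grid-searched, and that system is out of
scope here — but all are configurable. Every algorithm sees z-scored
features (mean/SD fitted on training data only; zero-SD columns pass
through), a single preprocessing path that KNN/LDA require and trees
tolerate.

Candidates are compared by stratified k-fold cross-validation on the
training split, with the fold count following the training positive count:
10 folds for ≥ 100 positives, 5 for 20–99, 2 otherwise (a documented
stand-in for an unpublished rule; the breakpoints are configurable, and the
count is clamped to the minority-class size on tiny datasets). The
**Opt-Classifier** is the candidate with the highest mean CV MCC; ties break
by mean CV AUROC and then by the fixed order RF > AdaBoost > KNN > LDA. The
winner is refitted on the full training split (standardisation refitted
too) and scored on the untouched 30% test split.

Confidence scores approximate the posterior probability of annotation: the
fraction of trees voting positive (RF), the fraction of positive neighbours
(KNN), the logistic transform 1/(1+exp(−2·margin)) of the boosting margin
(AdaBoost), and the LDA class posterior; all are clipped to [0, 1]. MCC is
evaluated at the fixed threshold "score strictly greater than 0.5".

## Metrics

* **MCC** = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
  marginal yields 0 (the standard convention for the undefined case).
* **AUROC**: rank-based (Mann–Whitney) with midrank tie handling.
* **Paired comparisons** across terms use the two-tailed Wilcoxon
  signed-rank test: zero differences discarded; exact null for n ≤ 25
  without tied absolute differences, otherwise the normal approximation
  with tie and continuity corrections.
* **Calibration**: for thresholds 0.00–0.95 in steps of 0.05, precision
  = TP/(TP+FP) among predictions scoring strictly above the threshold;
  Pearson's r between retained thresholds and precisions (reported as
  degenerate when fewer than three thresholds survive or precision is
  constant).
* **Group summary tables** average per-term MCC/AUROC by feature group,
  algorithm and namespace; the Opt-Classifier column is the mean of the
  per-term maximum across the four algorithms and therefore dominates every
  single-algorithm column by construction.

## Forest importance and RFI

For a trained random forest, the importance of feature *f* is the mean over
trees of the total weighted Gini impurity decrease at nodes splitting on
*f*, each node weighted by the fraction of the tree's bootstrap sample
reaching it:

    FI_f = (1/n_trees) · Σ_τ Σ_{j∈τ, split on f} (n_j/n_root) ·
           [ i(j) − (n_L/n_j)·i(L) − (n_R/n_j)·i(R) ]

This is textbook mean-decrease-impurity; the per-node weighting is the only
reading of "impurity decrease times the proportion of instances" that
reduces to it, and per-tree contributions are retained for audit. A
`denominator="dataset"` switch divides by the dataset size instead of the
root's bootstrap weight; with default bootstrap sizing the two coincide.

The **relative feature importance** of an expression feature compares its
FI to the global maximum over all features and the local maximum over
expression features:

    RFI_f = √( (FI_f / FI_max_global) · (FI_f / FI_max_local) )

RFI reaches 1.0 exactly when one expression feature attains both maxima.
Since RFI_f = FI_f / √(FI_max_global · FI_max_local) is linear in FI,
taking per-time-point maxima across the Num/Ave/Main groups commutes with
the RFI transform (asserted to 1e−12 in the tests), so the order of
collapsing and normalising does not matter. Collapsed profiles are
summarised per developmental stage by the stage maximum; the Results-style
1-based stage boundaries (embryo T1–T12, larva T13–T18, pupa T19–T24, adult
T25–T30) are used throughout. A term is flagged expression-relevant when
its maximum stage RFI strictly exceeds 0.7. Profiles of flagged terms are
hierarchically clustered (Euclidean distance, average linkage) on their
30-point RFI vectors.

Importance is normally read from the term's own trained forest. When the
Opt-Classifier is not a forest, the pipeline fits a forest on the same
training split purely for interpretation (forest models are the
interpretable ones in this design); an `rf_only` flag restricts the
analysis to forest-selected terms instead.

**Limitation — RFI needs a dominant signal.** RFI is a ratio to the global
maximum importance. For a term with *no* signal anywhere, all importances
are comparable noise, the local expression maximum sits close to the global
maximum, and √(L_max/G_max) lands around 0.8–0.9 — above the 0.7 screen.
The screen therefore distinguishes *where* a learnable term's signal lives
(expression vs sequence); it is not a test against a no-signal null. The
sequence-driven contrast (strong sequence signal, no expression signal) is
the meaningful null and is the one exercised by the test suite.

## Synthetic benchmark generator

The generator emulates the shapes of the four real inputs with plantable
ground truth. Defaults, chosen once as realistic study conditions:

* 500 genes, one protein per gene, 1–3 transcripts per gene with distinct
  isoform lengths;
* baseline transcript expression log-normal with meanlog 1.0 and sdlog 1.0
  (right-skewed, like RNA-seq abundance estimates); sequence features
  standard normal, 258 columns;
* a three-namespace GO DAG, each namespace root → 2 mids → 2 leaves per mid
  (widen with `leaves_per_mid` when more planted terms are needed), with
  one `part_of` edge per namespace for relationship coverage;
* planted terms of 100 positives attach to leaves. Expression-driven terms
  add δ = 2.0 to the log-mean of *all* transcripts of positive genes at 3
  informative time-points inside one stage (shifting every isoform keeps
  Num class-uninformative, isolating the Ave/Main signal; shifts on the log
  scale keep expression positive). Sequence-driven terms shift 10 randomly
  chosen sequence features of positives by 1.5 SD. `mixed` plants both,
  `null` plants nothing.

Everything is deterministic under the config seed, and the emitted GAF
round-trips to exactly the manifest's positive sets. What the generator does
*not* emulate: the covariance structure of real developmental expression
(stage-autocorrelated, shared regulons), isoform-level quantification
noise, the real GO DAG's depth and fan-out, and annotation incompleteness.
Passing tests therefore demonstrate that the machinery recovers signal it
was designed to detect under clean conditions, not field performance on
real fly data.

## Pipeline, determinism and problem sizes

The pipeline stages (simulate → features → build → train → predict →
evaluate → importance) each read and write files under one run directory,
so interrupted runs resume: a stage reruns only when an output is missing
or an upstream dependency reran. A single root seed derives per-stage seeds
by fixed offsets and per-term seeds from the term's position in the sorted
term list; with a fixed config two runs are byte-identical in their
prediction and RFI files (fixed 4- and 6-decimal formatting).

The default per-namespace training groups follow the best-performing
combinations: Seq+Num+Ave+Main for BP and MF, Seq+Ave+Main for CC.

The test suite exercises the stochastic properties at desk scale, a choice
made once when the suite was designed: feature-group contrasts use five
benchmark replicates of 500 proteins with six expression-driven, six
sequence-driven and two mixed terms each (forests of 200 trees); RFI
recovery uses four replicates with five single-time-point expression terms
and five sequence-only terms each; pipeline runs in tests use 120–150 genes
with reduced ensemble sizes. Library defaults (500 trees, 200 learners)
are unchanged.

## Numerical choices and degenerate inputs

* Zero-SD features standardise with divisor 1 (constant columns carry no
  information either way).
* MCC with any zero marginal is 0; an all-zero confusion table is an error.
* AUROC and calibration require both classes; single-class held-out CV
  folds score AUROC 0.5 / MCC 0 and are logged.
* Wilcoxon with all-zero differences warns and returns p = 1.
* `relative_importance` raises on an all-zero FI map and returns all-zero
  RFI when only the expression block is zero.
* Equivalence classes for Num use chained tolerance (sorted gaps >
  tolerance start a new class), making the count order-independent.
* Ties in main-transcript selection terminate in a lexicographic id
  comparison, so selection is total and reproducible.
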