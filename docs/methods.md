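# Methods

## Model and assumptions

The package treats next-gene recommendation as supervised link ranking
over the narrative order of experiments. Its core assumptions are:

* **Narrative order ≈ experimental order.** Within one article's result
  section, the order in which experiments are described approximates the
  order in which they were performed — reliably so for adjacent
  experiments on *different* genes, far less so for same-gene
  adjacencies, which often re-describe one experiment. Training therefore
  uses only different-gene adjacencies; `sequentiality_stats` quantifies
  this with a proportion and a percentile-bootstrap CI over the audited
  Bernoulli outcomes (10,000 resamples by default).
* **Functional modularity.** Genes analyzed in succession tend to belong
  to a common functional module, so evidence of shared annotation,
  correlated profiles, similar text embeddings and network proximity is
  predictive of the next target.
* **Single-sentence relations.** A gene–experiment relation is asserted
  only when gene and method co-occur in one sentence; cross-sentence
  relations are out of scope. The relation classifier is a contract
  (`score(masked sentence) → [0, 1]`); the shipped baselines are
  deterministic (accept-all, nearest-gene-to-method), and any stronger
  model can be plugged in without changing downstream code.

## Extraction details

Dictionary matching is a hand-rolled Aho–Corasick automaton (no external
matcher dependency). Matching is case-insensitive with canonical-case
resolution, anchored at word boundaries (a candidate span is rejected if
an alphanumeric character abuts either end), with overlaps resolved
longest-match-first, leftmost on ties. Surfaces shorter than `min_length`
(default 3) or in the stopword set are excluded; a surface claimed by two
gene records is ambiguous and dropped with a warning count. Each
occurrence of a repeated gene generates its own candidates. Masking
replaces the later span first so offsets stay valid; unmasking is exact
and round-trips byte-identically. Mentions are ordered per article by
(sentence index, gene start, method start) and numbered from 0; the
acceptance threshold on the relation score defaults to 0.5.

## Pairs, splits, negatives

`build_pairs` emits each within-article adjacency once and never crosses
article boundaries. The temporal split assigns year ≤ 2018 to train,
2019 to validation, ≥ 2020 to test; boundaries must be strictly
increasing. Negative sampling keeps gene_prev and redraws gene_next
uniformly from the universe, rejecting draws that (a) collide with any
positive tuple in the *global* positive set (a per-article scope is
available via `collision_scope`), (b) equal gene_prev, or (c) duplicate
an earlier draw for the same positive — so one positive's negatives are
distinct tuples. Ratio defaults to 3. If fewer legal replacements exist
than requested, the sampler raises an error naming the positive rather
than silently under-sampling.

## Feature encoding

Schema layout is frozen at fit time: categorical sources in declared
order with terms lexicographic (three slots per term: both / prev-only /
next-only), then numerical sources (one Pearson slot each), then
embedding sources (one cosine slot each); total dimension
3·T + N_num + N_emb. Numerical slots use pairwise-complete observations
when profiles contain missing entries, require ≥ 3 complete sample pairs,
and fall back to 0.0 — the shared "no evidence" point — for missing
genes, zero-variance profiles and zero-norm vectors. Terms annotating
fewer than `min_genes` genes (default 10) are dropped before freezing;
sparse-dictionary loading tables convert to categorical annotations at
|loading| > 0.1 (strict). Chromosome arms are an ordinary categorical
source whose terms are arms ("17p"). Unseen genes at inference encode as
all-zero rows with a warning. The batch transform is fully vectorized and
is verified in the tests against the scalar reference encoders.

## Models

`PairRanker` wraps one of seven algorithms (XGBoost gradient boosting,
logistic regression, SVM with probability outputs, random forest, MLP,
Gaussian naive Bayes, k-NN) behind a common fit/predict_proba surface;
library defaults are used (XGBoost: 200 trees) with the seed threaded
through, and the resolved hyperparameters are recorded on the fitted
artifact. Scores are raw probabilities; no calibration. The
literature-frequency baseline ranks genes by their pre-split experiment
counts and is query-independent. The next-method predictor is a
multiclass logistic regression over the closed 20-category set; its
output is always a simplex over all 20 categories (unseen categories get
probability 0) with argmax ties broken by fixed category order.

## Attribution

Explanations are Shapley values estimated by permutation sampling: per
permutation a background row is drawn, features are switched to the
instance values in permutation order, and marginal score changes are
accumulated (one batched model call of m+1 rows per permutation). The
telescoping sum makes the efficiency identity — contributions sum to
score(x) minus the mean sampled background score — hold exactly at any
number of permutations; the per-feature estimates converge to the exact
subset-enumeration values, which the tests verify on ≤ 6-feature models.
The default background is a seeded sample of training rows (100 in the
pipeline); contributions can be grouped by source for summary displays.

## Evaluation

AUROC is the Mann–Whitney probability that a random positive outscores a
random negative (ties ½), computed via `sklearn.metrics.roc_auc_score`
and cross-checked in the tests against a brute-force pairwise oracle.
AUROC@k adds uniform tie-breaking jitter in (0, 1e-10) — drawn once per
ranking from a dedicated seeded generator, before zeroing — re-ranks,
zeroes scores below rank k, and applies plain AUROC. Candidates that
followed the query in the training period but not in the evaluation
period are neither positive nor negative and are removed before scoring;
queries left with zero positives are skipped and counted.

RWR iterates r ← (1−c)·P·r + c·e with P = W D⁻¹ the column-stochastic
transition matrix of the weighted undirected network, restart probability
c = 0.15, L1 convergence at 1e-9, max 1000 iterations (error on
non-convergence, with the residual). This propagation conserves
probability mass, so the stationary vector is a distribution; nodes
outside the seed's component get proximity 0 and are flagged, and an
isolated seed degenerates to the indicator vector with a warning. The
iterative solution is oracle-checked against a dense linear solve on
graphs ≤ 50 nodes. When proximities are exported as model features, an
integration cutoff zeroes values below threshold (STRING-like 0.0005,
FunCoup-like 0.001 in the source material; configurable here). Model
comparison uses two-sided Mann–Whitney U tests Bonferroni-corrected over
all reported pairs, with percentile-bootstrap 95% CIs of per-model means
and paired mean differences (10,000 resamples).

## Synthetic world

The generator emulates exactly the structure the method exploits: genes
partitioned into modules; per-module term sets carried by members with
probability 1 − annotation_noise and leaking to non-members at
annotation_noise; profiles mixing a module latent with independent noise
(module_correlation sets the latent share of variance); embeddings as
module centroid + isotropic noise; a network dense within modules
(p = 0.6, weights 0.5–1) and sparse between (p = 0.01, weights
0.05–0.3); and articles that pick a home module and walk through it with
probability within_module_prob = 0.9 per step, rendered as templated
sentences with exactly one gene and one method term each. Defaults: 300
protein-coding genes (plus 10 pseudogenes exercising the
protein-coding-universe filter), 15 modules, 400 articles of 3–8
experiments, years 2015–2022 uniform, profile length 50, embedding
dimension 100. Sizes are chosen so the full end-to-end experiment runs
in seconds on one CPU while leaving every split non-empty.

What the fixture deliberately does **not** emulate: natural language
variation (templates are trivial by design, so extraction tests measure
matching correctness rather than NLP robustness), publication bias and
popularity skew, gene multifunctionality, release-dependent source
dimensions, and cross-sentence relations. Passing end-to-end tests
therefore demonstrate that the machinery recovers planted module
structure under clean conditions, not that any particular accuracy will
transfer to real literature corpora.

## Known limitations

* The relation-extraction baselines are intentionally weak; real corpora
  need a trained classifier behind the pluggable contract.
* The frequency baseline is uninformative on the synthetic world because
  article counts are near-uniform across modules; on real literature it
  is a much stronger comparator.
* AUROC against held-out partners is an approximation: a suggestion
  absent from later articles is not necessarily a bad target.
* Raw-score comparators consume precomputed pairwise tables; the
  comparators' internal scoring (semantic similarity, pfc integration)
  is out of scope.
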