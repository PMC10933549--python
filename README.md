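# nextgene

**nextgene** suggests target genes for the *next* molecular-biology
experiment. After a researcher finishes an experiment on gene *A*, the
natural question is which gene to analyze next — a decision normally made
by combing through literature and a pile of biomedical databases. This
package reconstructs that decision process from the literature itself: it
mines ordered experiment descriptions out of article text, learns from the
sequence in which genes were actually analyzed, and ranks the whole gene
universe for any query gene. It is aimed at computational biologists who
want the full pipeline — extraction, training-set construction, feature
integration, ranking and evaluation — as a reproducible library rather
than a web service.

## The method

1. **Experiment extraction.** Gene names (symbols + aliases, with a
   minimum length of 3 characters and a stopword filter) and
   experiment-method terms are dictionary-matched in each sentence with an
   Aho–Corasick automaton. Every (gene, method) co-occurrence becomes a
   candidate relation; the candidate is masked (`[EXPE] of [GENE] …`) and
   scored by a pluggable relation classifier (deterministic baselines
   ship; any `score(masked) → [0, 1]` model plugs in). Accepted mentions
   form an ordered per-article *experiment list*.
2. **Consecutive pairs.** Adjacent experiments on *different* genes within
   one article yield ordered training tuples (gene_prev, gene_next) — a
   manual audit shows different-gene adjacencies reflect genuinely
   sequential experiments 91.7 % of the time (same-gene: 64.7 %). Pairs
   are split temporally (train ≤ 2018, validation 2019, test ≥ 2020) and
   three negatives per positive are sampled by corrupting gene_next.
3. **Pair features.** Each tuple is encoded against heterogeneous
   sources: every categorical term (GO-like, phenotype, interaction
   partner, chromosome arm, regulator) occupies three 0/1 slots —
   (1,0,0) both genes annotated, (0,1,0) previous only, (0,0,1) next only
   — while each numerical profile source contributes one Pearson-*r* slot
   and each embedding source one cosine-similarity slot
   (dimension = 3·T + N_num + N_emb). Terms must annotate ≥ 10 genes;
   sparse-dictionary loadings count as annotations when |loading| > 0.1.
4. **Ranking and evaluation.** A binary classifier (XGBoost by default;
   six alternatives) scores every (query, candidate) tuple; candidates
   are ranked by probability. Rankings are scored per query with
   **AUROC@k**: jitter in (0, 1e-10) breaks ties, scores below rank *k*
   are zeroed, and the AUROC is computed against the genes actually
   analyzed after the query in held-out years. Comparators include a
   literature-frequency baseline, raw pairwise link scores, and random
   walk with restart, r ← (1−c)·P·r + c·e, on weighted gene networks.
5. **Explanation.** Per-suggestion feature attributions are Shapley values
   estimated by permutation sampling (checked against exact subset
   enumeration on small models).

A synthetic-world generator plants functional-module structure in every
source type so the entire pipeline runs and is validated with no external
downloads.

## Worked example

```python
from nextgene import SimConfig
from nextgene.pipeline import run_experiment
from nextgene.model import rank_genes

result = run_experiment(SimConfig(seed=0), seed=0)
print(result.mean_auroc_at_k("ranker", 100))

ranking = rank_genes(result.ranker, "SYG0010",
                     result.world.coding_genes, result.featurizer)
for gene, score, rank in ranking.top(5):
    print(rank, gene, round(score, 3))
```

On the default synthetic world (300 genes in 15 modules, 400 articles)
this prints:

```
training pairs: 834 positives
evaluated queries: 262
ranker     mean AUROC@100: 0.878
frequency  mean AUROC@100: 0.495
RWR        mean AUROC@100: 0.877

top 5 suggestions after an experiment on SYG0010:
  1. SYG0220  score=0.999  same_module=True
  2. SYG0250  score=0.998  same_module=True
  3. SYG0190  score=0.998  same_module=True
  4. SYG0115  score=0.997  same_module=True
  5. SYG0295  score=0.995  same_module=True
```

The trained ranker recovers the planted module structure — all top
suggestions share the query's functional module, and its mean AUROC@100
(0.878) far exceeds the query-independent frequency baseline (0.495) —
while the RWR comparator on the module-structured network performs
similarly, as expected when network and narrative encode the same
modules.

A `nextgene` console script exposes the same steps over files:
`nextgene simulate`, `extract`, `pairs`, `train`, `rank`, `rwr`.

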