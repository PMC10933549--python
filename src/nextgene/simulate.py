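"""Self-contained synthetic world with planted functional modules.

The generator emulates the statistical structure the recommender
exploits: genes work in functional modules, and within one article the
narrative of experiments tends to walk inside a single module.  The world
comprises a gene nomenclature table, categorical annotation sources whose
terms are owned by modules, numerical profiles correlated within modules,
embeddings clustered around module centroids, a gene network dense within
modules, and a corpus of articles whose sentences mention one gene and
one experiment method each (templated so dictionary matching is exact —
extraction correctness, not NLP, is what the fixture exercises).

The module assignment is ground truth: it is never exposed to the models
and exists only so tests can verify that every source carries the planted
signal and that the end-to-end pipeline recovers it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import METHOD_CATEGORIES, GeneRecord, MethodTerm
from .evaluation import GeneNetwork
from .features import CategoricalSource, EmbeddingSource, NumericalSource
from .pairs import ExperimentPair

#: One unambiguous surface term per method category.
METHOD_SURFACES: dict[str, str] = {
    "knockdown/knockout": "knockdown",
    "overexpression": "overexpression",
    "immunofluorescence": "immunofluorescence",
    "protein-protein interaction": "co-immunoprecipitation",
    "RT-PCR or qPCR": "quantitative PCR",
    "bioinformatics": "bioinformatic analysis",
    "immunohistochemistry": "immunohistochemistry",
    "next generation sequencing": "RNA sequencing",
    "rescue experiment": "rescue experiment",
    "protein structure": "crystallography",
    "FISH": "fluorescence in situ hybridization",
    "screening": "genetic screening",
    "mass spectrometry": "mass spectrometry",
    "super-resolution microscopy": "super-resolution microscopy",
    "electron microscopy": "electron microscopy",
    "GWAS": "genome-wide association study",
    "live-imaging": "live-cell imaging",
    "Xray-flattering": "X-ray scattering",
    "circular dichroism": "circular dichroism",
    "others": "microinjection",
}

_TEMPLATES = (
    "{Method} of {gene} was performed.",
    "We next performed {method} of {gene}.",
    "{Method} analysis of {gene} revealed a clear phenotype.",
)

_ARMS = tuple(f"{c}{a}" for c in range(1, 23) for a in "pq")


@dataclass
class SimConfig:
    """Parameters of the synthetic world.

    Defaults define the reference study conditions used throughout the
    test suite and the acceptance run.
    """

    n_genes: int = 300
    n_modules: int = 15
    n_articles: int = 400
    experiments_per_article: tuple[int, int] = (3, 8)
    within_module_prob: float = 0.9
    terms_per_module: int = 6
    annotation_noise: float = 0.05
    n_noncoding: int = 10
    profile_length: int = 50
    module_correlation: float = 0.7
    embedding_dim: int = 100
    embedding_noise: float = 0.6
    edge_prob_within: float = 0.6
    edge_prob_between: float = 0.01
    year_range: tuple[int, int] = (2015, 2022)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules > self.n_genes:
            raise ValueError("more modules than genes")
        lo, hi = self.experiments_per_article
        if not (1 <= lo <= hi):
            raise ValueError("empty experiments-per-article range")
        if not (self.year_range[0] <= self.year_range[1]):
            raise ValueError("empty year range")
        for p in (self.within_module_prob, self.annotation_noise,
                  self.module_correlation, self.edge_prob_within, self.edge_prob_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimWorld:
    """Generated fixture world plus its withheld ground truth."""

    config: SimConfig
    gene_records: list[GeneRecord]
    method_terms: list[MethodTerm]
    module_of: dict[str, int]
    categorical_sources: list[CategoricalSource]
    numerical_sources: list[NumericalSource]
    embedding_sources: list[EmbeddingSource]
    network: GeneNetwork
    corpus: list[tuple[str, int, list[str]]]
    article_log: list[dict] = field(repr=False)

    @property
    def coding_genes(self) -> list[str]:
        return [g.symbol for g in self.gene_records if g.locus_group == "protein-coding gene"]

    def write(self, out_dir: str | Path) -> None:
        from . import io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_gene_table(self.gene_records, out / "genes.tsv")
        io.write_method_table(self.method_terms, out / "methods.tsv")
        io.write_corpus(self.corpus, out / "corpus.jsonl")
        io.write_annotations(self.categorical_sources, out / "annotations.tsv")
        for src in self.numerical_sources:
            io.write_profiles(src, out / f"profiles_{src.name}.tsv")
        for src in self.embedding_sources:
            io.write_embeddings(src, out / f"embeddings_{src.name}.tsv")
        io.write_network(self.network, out / "network.tsv")
        io.write_truth(self, out / "truth.json")


def generate_world(config: SimConfig = SimConfig()) -> SimWorld:
    """Deterministically generate the full fixture world from a seed."""
    rng = np.random.default_rng(config.seed)
    n, k = config.n_genes, config.n_modules

    symbols = [f"SYG{i:04d}" for i in range(n)]
    modules = np.arange(n) % k  # balanced assignment
    module_of = {g: int(m) for g, m in zip(symbols, modules)}
    members: list[list[str]] = [[g for g, m in zip(symbols, modules) if m == mi] for mi in range(k)]

    gene_records = [
        GeneRecord(
            symbol=g,
            aliases=frozenset({f"sg{i:04d}-alt"}),
            locus_group="protein-coding gene",
            chromosome_arm=_ARMS[module_of[g] % len(_ARMS)],
        )
        for i, g in enumerate(symbols)
    ]
    gene_records += [
        GeneRecord(symbol=f"SYGNC{i:02d}", aliases=frozenset(), locus_group="pseudogene",
                   chromosome_arm="")
        for i in range(config.n_noncoding)
    ]
    method_terms = [MethodTerm(name=METHOD_SURFACES[c], category=c) for c in METHOD_CATEGORIES]

    # --- categorical sources: module-owned term sets with leak noise
    def term_source(name: str, n_terms: int) -> CategoricalSource:
        annotations: dict[str, set[str]] = {g: set() for g in symbols}
        for mi in range(k):
            terms = [f"{name.upper()}:M{mi:03d}T{t}" for t in range(n_terms)]
            for g in symbols:
                p = 1.0 - config.annotation_noise if module_of[g] == mi else config.annotation_noise
                hit = rng.random(n_terms) < p
                annotations[g].update(t for t, h in zip(terms, hit) if h)
        return CategoricalSource(name, annotations)

    go_like = term_source("go_like", config.terms_per_module)
    hpo_like = term_source("hpo_like", max(2, config.terms_per_module // 2))
    arm_source = CategoricalSource(
        "chromosome_arm",
        {r.symbol: {r.chromosome_arm} for r in gene_records if r.chromosome_arm},
    )

    # --- numerical sources: module latent + independent noise
    def profile_source(name: str, length: int) -> NumericalSource:
        rho = config.module_correlation
        latents = rng.normal(size=(k, length))
        profiles = {}
        for g in symbols:
            eps = rng.normal(size=length)
            profiles[g] = np.sqrt(rho) * latents[module_of[g]] + np.sqrt(1 - rho) * eps
        return NumericalSource(name, profiles)

    expression = profile_source("expression", config.profile_length)
    essentiality = profile_source("essentiality", config.profile_length)

    # --- embeddings: module centroid + isotropic noise
    centroids = rng.normal(size=(k, config.embedding_dim))
    vectors = {
        g: centroids[module_of[g]] + config.embedding_noise * rng.normal(size=config.embedding_dim)
        for g in symbols
    }
    embedding = EmbeddingSource("text_embedding", vectors)

    # --- network: dense within modules, sparse between
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            same = modules[i] == modules[j]
            p = config.edge_prob_within if same else config.edge_prob_between
            if rng.random() < p:
                w = rng.uniform(0.5, 1.0) if same else rng.uniform(0.05, 0.3)
                edges.append((symbols[i], symbols[j], float(w)))
    network = GeneNetwork.from_edges(edges, name="coexpression_net")

    # --- corpus: per-article ordered experiment narratives
    lo, hi = config.experiments_per_article
    y0, y1 = config.year_range
    cat_probs = np.full((k, len(METHOD_CATEGORIES)), 0.4 / (len(METHOD_CATEGORIES) - 1))
    for mi in range(k):
        cat_probs[mi, mi % len(METHOD_CATEGORIES)] = 0.6
    corpus: list[tuple[str, int, list[str]]] = []
    article_log: list[dict] = []
    for a in range(config.n_articles):
        article_id = f"ART{a:04d}"
        year = int(rng.integers(y0, y1 + 1))
        home = int(rng.integers(k))
        n_exp = int(rng.integers(lo, hi + 1))
        genes: list[str] = []
        cats: list[str] = []
        for _ in range(n_exp):
            if rng.random() < config.within_module_prob:
                gene = members[home][int(rng.integers(len(members[home])))]
            else:
                gene = symbols[int(rng.integers(n))]
            genes.append(gene)
            cats.append(METHOD_CATEGORIES[rng.choice(len(METHOD_CATEGORIES), p=cat_probs[home])])
        sentences = ["We investigated the underlying mechanism."]
        for gene, cat in zip(genes, cats):
            method = METHOD_SURFACES[cat]
            tmpl = _TEMPLATES[int(rng.integers(len(_TEMPLATES)))]
            sentences.append(
                tmpl.format(gene=gene, method=method, Method=method[0].upper() + method[1:])
            )
        corpus.append((article_id, year, sentences))
        article_log.append(
            {"article_id": article_id, "year": year, "home_module": home,
             "genes": genes, "categories": cats}
        )

    return SimWorld(
        config=config,
        gene_records=gene_records,
        method_terms=method_terms,
        module_of=module_of,
        categorical_sources=[go_like, hpo_like, arm_source],
        numerical_sources=[expression, essentiality],
        embedding_sources=[embedding],
        network=network,
        corpus=corpus,
        article_log=article_log,
    )


def ground_truth_pairs(world: SimWorld) -> list[ExperimentPair]:
    """Exact census of different-gene consecutive pairs per article."""
    out = []
    for log in world.article_log:
        genes: Sequence[str] = log["genes"]
        for a, b in zip(genes, genes[1:]):
            if a != b:
                out.append(
                    ExperimentPair(gene_prev=a, gene_next=b,
                                   article_id=log["article_id"], year=log["year"], label=1)
                )
    return out
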