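"""Readers and writers for the package's plain-text interchange formats.

All tables are TSV; the corpus is JSONL (one article per line with its
ordered sentences); feature schemas and the synthetic ground truth are
JSON.  Readers return the package's in-memory containers so every file a
generator writes round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import ExperimentMention, GeneRecord, MethodTerm
from .evaluation import GeneNetwork
from .features import CategoricalSource, EmbeddingSource, NumericalSource
from .pairs import ExperimentPair

# --- gene nomenclature table ------------------------------------------------


def write_gene_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "symbol": [r.symbol for r in records],
            "aliases": ["|".join(sorted(r.aliases)) for r in records],
            "locus_group": [r.locus_group for r in records],
            "location": [r.chromosome_arm for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        GeneRecord(
            symbol=row.symbol,
            aliases=frozenset(a for a in row.aliases.split("|") if a),
            locus_group=row.locus_group,
            chromosome_arm=row.location,
        )
        for row in df.itertuples()
    ]


# --- method term table ------------------------------------------------------


def write_method_table(terms: Sequence[MethodTerm], path: str | Path) -> None:
    pd.DataFrame(
        {"term": [t.name for t in terms], "category": [t.category for t in terms]}
    ).to_csv(path, sep="\t", index=False)


def read_method_table(path: str | Path) -> list[MethodTerm]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [MethodTerm(name=row.term, category=row.category) for row in df.itertuples()]


# --- corpus -----------------------------------------------------------------


def write_corpus(articles: Iterable[tuple[str, int, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for article_id, year, sentences in articles:
            fh.write(
                json.dumps(
                    {"article_id": article_id, "year": year, "sentences": sentences},
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus(path: str | Path) -> list[tuple[str, int, list[str]]]:
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            out.append((rec["article_id"], int(rec["year"]), list(rec["sentences"])))
    return out


# --- experiment lists and pairs ---------------------------------------------

_EXP_COLUMNS = ["article_id", "year", "sentence_index", "order_index", "gene", "method", "score"]


def write_experiments(mentions: Sequence[ExperimentMention], path: str | Path) -> None:
    pd.DataFrame(
        [
            (m.article_id, m.year, m.sentence_index, m.order_index, m.gene_symbol,
             m.method_name, m.relation_score)
            for m in mentions
        ],
        columns=_EXP_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_experiments(path: str | Path) -> list[ExperimentMention]:
    df = pd.read_csv(path, sep="\t")
    return [
        ExperimentMention(
            article_id=str(row.article_id),
            year=int(row.year),
            sentence_index=int(row.sentence_index),
            order_index=int(row.order_index),
            gene_symbol=str(row.gene),
            method_name=str(row.method),
            relation_score=float(row.score),
        )
        for row in df.itertuples()
    ]


def write_pairs(pairs: Sequence[ExperimentPair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.gene_prev, p.gene_next, p.article_id, p.year, p.label) for p in pairs],
        columns=["gene_prev", "gene_next", "article_id", "year", "label"],
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[ExperimentPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        ExperimentPair(
            gene_prev=str(row.gene_prev),
            gene_next=str(row.gene_next),
            article_id=str(row.article_id),
            year=int(row.year),
            label=int(row.label),
        )
        for row in df.itertuples()
    ]


# --- feature sources --------------------------------------------------------


def write_annotations(sources: Sequence[CategoricalSource], path: str | Path) -> None:
    rows = []
    for src in sources:
        for gene in sorted(src.annotations):
            for term in sorted(src.annotations[gene]):
                rows.append((gene, term, src.name))
    pd.DataFrame(rows, columns=["gene", "term", "source"]).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, CategoricalSource]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    sources: dict[str, CategoricalSource] = {}
    for name, grp in df.groupby("source", sort=True):
        annotations: dict[str, set[str]] = {}
        for row in grp.itertuples():
            annotations.setdefault(row.gene, set()).add(row.term)
        sources[name] = CategoricalSource(str(name), annotations)
    return sources


def write_profiles(source: NumericalSource, path: str | Path) -> None:
    genes = sorted(source.profiles)
    mat = np.vstack([source.profiles[g] for g in genes]) if genes else np.zeros((0, 0))
    df = pd.DataFrame(mat, columns=[f"s{i}" for i in range(mat.shape[1])])
    df.insert(0, "gene", genes)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_profiles(path: str | Path, name: str | None = None) -> NumericalSource:
    df = pd.read_csv(path, sep="\t")
    name = name or Path(path).stem.removeprefix("profiles_")
    profiles = {
        str(row[0]): np.asarray(row[1:], dtype=float) for row in df.itertuples(index=False)
    }
    return NumericalSource(name, profiles)


def write_embeddings(source: EmbeddingSource, path: str | Path) -> None:
    genes = sorted(source.vectors)
    mat = np.vstack([source.vectors[g] for g in genes]) if genes else np.zeros((0, 0))
    df = pd.DataFrame(mat, columns=[f"d{i}" for i in range(mat.shape[1])])
    df.insert(0, "gene", genes)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_embeddings(path: str | Path, name: str | None = None) -> EmbeddingSource:
    df = pd.read_csv(path, sep="\t")
    name = name or Path(path).stem.removeprefix("embeddings_")
    vectors = {
        str(row[0]): np.asarray(row[1:], dtype=float) for row in df.itertuples(index=False)
    }
    return EmbeddingSource(name, vectors)


# --- networks and pairwise score tables -------------------------------------


def write_network(network: GeneNetwork, path: str | Path) -> None:
    rows = sorted(
        (min(a, b), max(a, b), d.get("weight", 1.0))
        for a, b, d in network.graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["geneA", "geneB", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_network(path: str | Path, name: str | None = None) -> GeneNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = [(str(r.geneA), str(r.geneB), float(r.weight)) for r in df.itertuples()]
    return GeneNetwork.from_edges(edges, name=name or Path(path).stem)


def read_pair_scores(path: str | Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    return {(str(r[0]), str(r[1])): float(r[2]) for r in df.itertuples(index=False)}


# --- synthetic ground truth -------------------------------------------------


def write_truth(world, path: str | Path) -> None:
    truth = {
        "module_of": world.module_of,
        "articles": world.article_log,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in vars(world.config).items()},
    }
    Path(path).write_text(json.dumps(truth, indent=1))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
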