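"""Pairwise feature encoding from heterogeneous gene-level sources.

An ordered gene pair (previous-experiment gene, next-experiment gene) is
encoded against three kinds of evidence:

* **categorical sources** (ontology terms, phenotypes, interaction
  partners, chromosome arms, regulators ...): each retained term occupies
  three 0/1 slots — (1,0,0) both genes annotated, (0,1,0) only the
  previous gene, (0,0,1) only the next gene, (0,0,0) neither;
* **numerical sources** (expression or essentiality profiles over a shared
  sample axis): one slot per source holding the Pearson correlation of the
  two genes' profiles;
* **embedding sources** (e.g. word vectors of gene names): one slot per
  source holding the cosine similarity of the two genes' vectors.

Terms annotating fewer than ``min_genes`` genes (default 10) are dropped
before the schema is frozen; sparse-dictionary loading tables become a
categorical source by keeping |loading| > 0.1 relationships.  Missing
genes, zero-variance profiles and zero-norm vectors all encode as 0.0,
the "no evidence" point of every slot.

:class:`PairFeaturizer` is the sklearn-style transformer that freezes the
column schema at fit time and encodes pair batches fully vectorized; the
module-level functions are thin scalar reference wrappers over the same
rules.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .pairs import ExperimentPair

CATEGORICAL_SLOTS = ("both", "prev_only", "next_only")


@dataclass
class CategoricalSource:
    """Gene → set-of-terms annotations from one database-like source."""

    name: str
    annotations: dict[str, set[str]]
    min_genes: int = 10

    def term_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for terms in self.annotations.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        return counts


@dataclass
class NumericalSource:
    """Gene → real-valued profile over a shared sample axis (e.g. TPM)."""

    name: str
    profiles: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.profiles.values()}
        if len(lengths) > 1:
            raise ValueError(f"profiles of source {self.name!r} have unequal lengths")
        if lengths and min(lengths) < 3:
            raise ValueError("profiles need >= 3 samples for a nondegenerate correlation")
        self.profiles = {g: np.asarray(v, dtype=float) for g, v in self.profiles.items()}


@dataclass
class EmbeddingSource:
    """Gene → dense embedding vector (uniform dimension)."""

    name: str
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.vectors = {g: np.asarray(v, dtype=float) for g, v in self.vectors.items()}
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"embedding source {self.name!r} has mixed dimensions")
        if self.vectors and not any(np.any(v) for v in self.vectors.values()):
            raise ValueError(f"embedding source {self.name!r} is all zeros")


def filter_terms(source: CategoricalSource, min_genes: int = 10) -> CategoricalSource:
    """Drop terms annotating fewer than ``min_genes`` genes."""
    counts = source.term_counts()
    keep = {t for t, c in counts.items() if c >= min_genes}
    filtered = {g: terms & keep for g, terms in source.annotations.items()}
    return CategoricalSource(source.name, {g: t for g, t in filtered.items()}, min_genes)


def webster_to_categorical(
    loadings: Mapping[tuple[str, str], float],
    threshold: float = 0.1,
    name: str = "webster",
) -> CategoricalSource:
    """Sparse-dictionary loadings → categorical annotations.

    A gene is annotated with an inferred function iff the magnitude of its
    loading strictly exceeds ``threshold`` (either sign).
    """
    annotations: dict[str, set[str]] = {}
    for (gene, function), loading in loadings.items():
        if abs(loading) > threshold:
            annotations.setdefault(gene, set()).add(function)
    return CategoricalSource(name, annotations)


@dataclass(frozen=True)
class FeatureSchema:
    """Frozen, ordered feature-column layout.

    Each column is (source_name, term_or_kind, slot): categorical terms
    occupy the three slots of :data:`CATEGORICAL_SLOTS`; numerical and
    embedding sources occupy one ``pearson``/``cosine`` slot each.
    """

    columns: tuple[tuple[str, str, str], ...]

    @property
    def dimension(self) -> int:
        return len(self.columns)

    def column_names(self) -> list[str]:
        return [f"{src}:{term}:{slot}" for src, term, slot in self.columns]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"columns": [list(c) for c in self.columns]}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        data = json.loads(Path(path).read_text())
        return cls(tuple(tuple(c) for c in data["columns"]))


def build_schema(
    categorical: Sequence[CategoricalSource] = (),
    numerical: Sequence[NumericalSource] = (),
    embedding: Sequence[EmbeddingSource] = (),
) -> FeatureSchema:
    """Freeze the column order: categorical (terms lexicographic, 3 slots
    each) in declared source order, then numerical, then embedding."""
    names = [s.name for s in (*categorical, *numerical, *embedding)]
    if len(set(names)) != len(names):
        raise ValueError("duplicate source names")
    columns: list[tuple[str, str, str]] = []
    for src in categorical:
        for term in sorted({t for terms in src.annotations.values() for t in terms}):
            for slot in CATEGORICAL_SLOTS:
                columns.append((src.name, term, slot))
    for src in numerical:
        columns.append((src.name, "profile", "pearson"))
    for src in embedding:
        columns.append((src.name, "vector", "cosine"))
    if not columns:
        warnings.warn("empty feature schema (no sources)", stacklevel=2)
    return FeatureSchema(tuple(columns))


# ---------------------------------------------------------------------------
# scalar reference encoders


def encode_categorical(
    gene_prev: str, gene_next: str, term: str, source: CategoricalSource
) -> tuple[int, int, int]:
    """(both, prev_only, next_only) membership triple for one term."""
    in_prev = term in source.annotations.get(gene_prev, ())
    in_next = term in source.annotations.get(gene_next, ())
    if in_prev and in_next:
        return (1, 0, 0)
    if in_prev:
        return (0, 1, 0)
    if in_next:
        return (0, 0, 1)
    return (0, 0, 0)


def encode_numerical(gene_prev: str, gene_next: str, source: NumericalSource) -> float:
    """Pearson r of the two genes' profiles over pairwise-complete samples.

    Missing gene, fewer than 3 complete sample pairs, or a zero-variance
    profile all yield 0.0.
    """
    a = source.profiles.get(gene_prev)
    b = source.profiles.get(gene_next)
    if a is None or b is None:
        return 0.0
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        return 0.0
    a, b = a[mask], b[mask]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def encode_embedding(gene_prev: str, gene_next: str, source: EmbeddingSource) -> float:
    """Cosine similarity of the two genes' vectors; 0.0 when undefined."""
    a = source.vectors.get(gene_prev)
    b = source.vectors.get(gene_next)
    if a is None or b is None:
        return 0.0
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


# ---------------------------------------------------------------------------
# vectorized transformer


class PairFeaturizer(TransformerMixin, BaseEstimator):
    """Encode ordered gene pairs as fixed-length feature vectors.

    Parameters
    ----------
    categorical_sources, numerical_sources, embedding_sources
        The evidence sources; categorical sources are term-filtered at fit
        time with ``min_genes``.
    min_genes
        Minimum number of annotated genes for a categorical term to enter
        the schema (default 10).

    Attributes
    ----------
    schema_ : FeatureSchema
        Frozen column layout (3 slots per retained categorical term, one
        per numerical/embedding source).
    gene_index_ : dict[str, int]
        Row index over the union of genes seen in any source; genes absent
        from every source encode as all-zero rows.
    """

    def __init__(
        self,
        categorical_sources: Sequence[CategoricalSource] = (),
        numerical_sources: Sequence[NumericalSource] = (),
        embedding_sources: Sequence[EmbeddingSource] = (),
        min_genes: int = 10,
    ):
        self.categorical_sources = categorical_sources
        self.numerical_sources = numerical_sources
        self.embedding_sources = embedding_sources
        self.min_genes = min_genes

    def fit(self, X=None, y=None) -> "PairFeaturizer":
        cats = [filter_terms(s, self.min_genes) for s in self.categorical_sources]
        nums = list(self.numerical_sources)
        embs = list(self.embedding_sources)
        self.schema_ = build_schema(cats, nums, embs)

        genes: set[str] = set()
        for s in cats:
            genes.update(s.annotations)
        for s in nums:
            genes.update(s.profiles)
        for s in embs:
            genes.update(s.vectors)
        order = sorted(genes)
        self.gene_index_ = {g: i for i, g in enumerate(order)}
        n = len(order)  # row n is the "unknown gene" all-missing row

        # categorical membership: (n+1, total_terms) boolean
        term_lists = []
        blocks = []
        for s in cats:
            terms = sorted({t for ts in s.annotations.values() for t in ts})
            term_lists.append(terms)
            tix = {t: j for j, t in enumerate(terms)}
            m = np.zeros((n + 1, len(terms)), dtype=bool)
            for g, ts in s.annotations.items():
                gi = self.gene_index_[g]
                for t in ts:
                    m[gi, tix[t]] = True
            blocks.append(m)
        self._cat_matrix = (
            np.concatenate(blocks, axis=1) if blocks else np.zeros((n + 1, 0), dtype=bool)
        )
        self._n_terms = self._cat_matrix.shape[1]

        # numerical profiles: list of (n+1, L) with NaN for missing genes
        self._profiles = []
        for s in nums:
            length = len(next(iter(s.profiles.values()))) if s.profiles else 3
            mat = np.full((n + 1, length), np.nan)
            for g, v in s.profiles.items():
                mat[self.gene_index_[g]] = v
            self._profiles.append(mat)

        # embeddings: unit-normalized, zero rows when missing/zero-norm
        self._embeddings = []
        for s in embs:
            dim = next(iter(s.vectors.values())).shape[0] if s.vectors else 1
            mat = np.zeros((n + 1, dim))
            for g, v in s.vectors.items():
                norm = np.linalg.norm(v)
                if norm > 0:
                    mat[self.gene_index_[g]] = v / norm
            self._embeddings.append(mat)
        return self

    def _indices(self, pairs) -> tuple[np.ndarray, np.ndarray]:
        unknown = len(self.gene_index_)
        prev_idx = np.empty(len(pairs), dtype=np.intp)
        next_idx = np.empty(len(pairs), dtype=np.intp)
        for i, p in enumerate(pairs):
            a, b = (p.gene_prev, p.gene_next) if isinstance(p, ExperimentPair) else p
            prev_idx[i] = self.gene_index_.get(a, unknown)
            next_idx[i] = self.gene_index_.get(b, unknown)
        return prev_idx, next_idx

    def transform(self, pairs: Sequence) -> np.ndarray:
        """Encode pairs (ExperimentPair or (prev, next) tuples) to a matrix."""
        if not hasattr(self, "schema_"):
            raise RuntimeError("PairFeaturizer is not fitted")
        ia, ib = self._indices(pairs)
        npairs = len(ia)
        X = np.zeros((npairs, self.schema_.dimension))

        if self._n_terms:
            A = self._cat_matrix[ia]
            B = self._cat_matrix[ib]
            cat = np.zeros((npairs, 3 * self._n_terms))
            cat[:, 0::3] = A & B
            cat[:, 1::3] = A & ~B
            cat[:, 2::3] = ~A & B
            X[:, : 3 * self._n_terms] = cat
        col = 3 * self._n_terms
        for mat in self._profiles:
            X[:, col] = _pairwise_pearson(mat, ia, ib)
            col += 1
        for mat in self._embeddings:
            X[:, col] = np.clip(np.einsum("ij,ij->i", mat[ia], mat[ib]), -1.0, 1.0)
            col += 1
        return X

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.schema_.column_names(), dtype=object)


def _pairwise_pearson(P: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Row-paired Pearson r over pairwise-complete entries, NaN-aware."""
    A, B = P[ia], P[ib]
    M = np.isfinite(A) & np.isfinite(B)
    A = np.where(M, A, 0.0)
    B = np.where(M, B, 0.0)
    n = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa = A.sum(axis=1)
        sb = B.sum(axis=1)
        cov = (A * B).sum(axis=1) - sa * sb / np.maximum(n, 1)
        va = (A * A).sum(axis=1) - sa * sa / np.maximum(n, 1)
        vb = (B * B).sum(axis=1) - sb * sb / np.maximum(n, 1)
        r = cov / np.sqrt(va * vb)
    bad = (n < 3) | ~np.isfinite(r)
    r = np.where(bad, 0.0, r)
    return np.clip(r, -1.0, 1.0)


def featurize(pairs: Sequence, featurizer: PairFeaturizer) -> np.ndarray:
    """One feature vector per pair, column-aligned to the fitted schema.

    Emits a warning for genes absent from every source (all-zero rows).
    """
    X = featurizer.transform(pairs)
    n_missing = int((X == 0).all(axis=1).sum())
    if n_missing:
        warnings.warn(f"{n_missing} pairs encode as all-zero rows", stacklevel=2)
    return X


def make_featurizer(
    categorical: Iterable[CategoricalSource] = (),
    numerical: Iterable[NumericalSource] = (),
    embedding: Iterable[EmbeddingSource] = (),
    min_genes: int = 10,
) -> PairFeaturizer:
    """Convenience constructor + fit in one call."""
    return PairFeaturizer(
        list(categorical), list(numerical), list(embedding), min_genes=min_genes
    ).fit()
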