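"""Extraction of gene–experiment mentions from article text.

The extraction pipeline mirrors how literature-mined experiment lists are
built: a dictionary automaton finds gene names and experiment-method terms
in each sentence, every (gene, method) co-occurrence becomes a candidate
relation, the candidate is masked with ``[GENE]``/``[EXPE]`` tokens and
handed to a pluggable relation classifier, and accepted candidates become
:class:`ExperimentMention` records ordered by document position.

The relation classifier is a contract: any object with a
``score(masked) -> float in [0, 1]`` method works.  Two deterministic
baselines ship here — :class:`AllPositiveClassifier` (every co-occurrence
is a relation; recall 1 by construction) and
:class:`NearestMethodClassifier` (only the gene nearest to the method term
is in relation with it).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Protocol

from ._ahocorasick import Automaton

GENE_TOKEN = "[GENE]"
METHOD_TOKEN = "[EXPE]"

#: Closed 20-label set of experiment-method categories.
METHOD_CATEGORIES: tuple[str, ...] = (
    "knockdown/knockout",
    "overexpression",
    "immunofluorescence",
    "protein-protein interaction",
    "RT-PCR or qPCR",
    "bioinformatics",
    "immunohistochemistry",
    "next generation sequencing",
    "rescue experiment",
    "protein structure",
    "FISH",
    "screening",
    "mass spectrometry",
    "super-resolution microscopy",
    "electron microscopy",
    "GWAS",
    "live-imaging",
    "Xray-flattering",
    "circular dichroism",
    "others",
)

_ARM_RE = re.compile(r"^\d{1,2}[pq]$|^[XY][pq]$")


@dataclass(frozen=True)
class GeneRecord:
    """One row of an HGNC-like nomenclature table."""

    symbol: str
    aliases: frozenset[str] = frozenset()
    locus_group: str = "protein-coding gene"
    chromosome_arm: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be nonempty")
        if self.symbol in self.aliases:
            raise ValueError(f"symbol {self.symbol!r} duplicated in its aliases")
        if self.chromosome_arm and not _ARM_RE.match(self.chromosome_arm):
            raise ValueError(f"malformed chromosome arm {self.chromosome_arm!r}")


@dataclass(frozen=True)
class MethodTerm:
    """An experiment-method surface term with its category label."""

    name: str
    category: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("method term must be nonempty")
        if self.category not in METHOD_CATEGORIES:
            raise ValueError(f"unknown method category {self.category!r}")


@dataclass
class TermIndex:
    """Dictionary of gene and method surface strings for sentence matching.

    Matching is case-insensitive, anchored at word boundaries, and resolves
    overlaps by longest match first, leftmost start on ties.  Aliases
    resolve to their canonical gene symbol; a surface string claimed by two
    different genes is ambiguous and excluded.
    """

    entries: dict[str, tuple[str, str]]  # lowercased surface -> (kind, canonical)
    min_length: int
    stopwords: frozenset[str]
    n_ambiguous: int = 0
    _automaton: Automaton | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self._automaton is None and self.entries:
            self._automaton = Automaton(sorted(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def find_matches(self, text: str) -> list[tuple[int, int, str, str]]:
        """Return non-overlapping matches as (start, end, kind, canonical)."""
        if not self.entries:
            return []
        low = text.lower()
        raw = []
        for start, end in self._automaton.iter_matches(low):
            if start > 0 and low[start - 1].isalnum():
                continue
            if end < len(low) and low[end].isalnum():
                continue
            raw.append((start, end))
        # longest wins; ties broken by leftmost start
        raw.sort(key=lambda se: (-(se[1] - se[0]), se[0]))
        chosen: list[tuple[int, int]] = []
        for start, end in raw:
            if all(end <= s or start >= e for s, e in chosen):
                chosen.append((start, end))
        chosen.sort()
        out = []
        for start, end in chosen:
            kind, canonical = self.entries[low[start:end]]
            out.append((start, end, kind, canonical))
        return out


def build_term_index(
    genes: Iterable[GeneRecord],
    methods: Iterable[MethodTerm],
    min_length: int = 3,
    stopwords: Iterable[str] = (),
) -> TermIndex:
    """Build the matching dictionary from gene and method term lists.

    Surface strings shorter than ``min_length`` and stopword-like terms are
    excluded to avoid false gene detection.  A surface mapping to two
    different gene symbols is dropped as ambiguous (counted, with a
    warning).
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    stop = frozenset(s.lower() for s in stopwords)
    entries: dict[str, tuple[str, str]] = {}
    ambiguous: set[str] = set()

    def admit(surface: str) -> str | None:
        if len(surface) < min_length:
            return None
        low = surface.lower()
        if low in stop:
            return None
        return low

    for rec in genes:
        for surface in {rec.symbol, *rec.aliases}:
            low = admit(surface)
            if low is None:
                continue
            prior = entries.get(low)
            if prior is not None and prior != ("gene", rec.symbol):
                ambiguous.add(low)
            else:
                entries[low] = ("gene", rec.symbol)
    for low in ambiguous:
        entries.pop(low, None)
    for term in methods:
        low = admit(term.name)
        if low is None:
            continue
        prior = entries.get(low)
        if prior is not None and prior[0] == "gene":
            # a method term colliding with a gene surface is ambiguous too
            ambiguous.add(low)
            entries.pop(low)
            continue
        entries[low] = ("method", term.name)
    if ambiguous:
        warnings.warn(
            f"{len(ambiguous)} ambiguous surface strings excluded from the term index",
            stacklevel=2,
        )
    return TermIndex(entries, min_length, stop, n_ambiguous=len(ambiguous))


@dataclass(frozen=True)
class CandidatePair:
    """A (gene, method) co-occurrence in one sentence, with spans."""

    sentence_text: str
    gene_span: tuple[int, int]
    method_span: tuple[int, int]
    gene_symbol: str
    method_name: str
    article_id: str = ""
    year: int = 0
    sentence_index: int = 0

    def __post_init__(self) -> None:
        for s, e in (self.gene_span, self.method_span):
            if not (0 <= s < e <= len(self.sentence_text)):
                raise ValueError(f"span ({s}, {e}) outside sentence bounds")
        gs, ge = self.gene_span
        ms, me = self.method_span
        if gs < me and ms < ge:
            raise ValueError("gene and method spans overlap")


@dataclass(frozen=True)
class MaskedSentence:
    """Candidate sentence with the gene and method replaced by tokens."""

    text: str
    provenance: CandidatePair

    def __post_init__(self) -> None:
        if self.text.count(GENE_TOKEN) != 1 or self.text.count(METHOD_TOKEN) != 1:
            raise ValueError("masked sentence must contain exactly one [GENE] and one [EXPE]")


def find_candidates(
    sentence_text: str,
    index: TermIndex,
    article_id: str = "",
    year: int = 0,
    sentence_index: int = 0,
) -> list[CandidatePair]:
    """All gene × method co-occurrences in one sentence.

    Returns the full cross product of gene matches and method matches,
    ordered by (gene start, method start); a sentence lacking either kind
    yields no candidates.
    """
    if not sentence_text:
        raise ValueError("sentence must be nonempty")
    matches = index.find_matches(sentence_text)
    gene_hits = [(s, e, c) for s, e, k, c in matches if k == "gene"]
    method_hits = [(s, e, c) for s, e, k, c in matches if k == "method"]
    out = []
    for gs, ge, gene in gene_hits:
        for ms, me, method in method_hits:
            out.append(
                CandidatePair(
                    sentence_text=sentence_text,
                    gene_span=(gs, ge),
                    method_span=(ms, me),
                    gene_symbol=gene,
                    method_name=method,
                    article_id=article_id,
                    year=year,
                    sentence_index=sentence_index,
                )
            )
    out.sort(key=lambda c: (c.gene_span[0], c.method_span[0]))
    return out


def mask_candidate(candidate: CandidatePair) -> MaskedSentence:
    """Replace the gene surface by ``[GENE]`` and the method by ``[EXPE]``."""
    text = candidate.sentence_text
    spans = sorted(
        [(candidate.gene_span, GENE_TOKEN), (candidate.method_span, METHOD_TOKEN)],
        key=lambda it: it[0][0],
        reverse=True,
    )
    for (s, e), token in spans:
        text = text[:s] + token + text[e:]
    return MaskedSentence(text=text, provenance=candidate)


def unmask(masked: MaskedSentence) -> str:
    """Restore the original sentence from a masked candidate."""
    cand = masked.provenance
    gene_surface = cand.sentence_text[slice(*cand.gene_span)]
    method_surface = cand.sentence_text[slice(*cand.method_span)]
    text = masked.text.replace(GENE_TOKEN, gene_surface, 1)
    return text.replace(METHOD_TOKEN, method_surface, 1)


class RelationClassifier(Protocol):
    """Contract for gene–experiment relation scoring on masked sentences."""

    def score(self, masked: MaskedSentence) -> float:  # pragma: no cover
        ...


class AllPositiveClassifier:
    """Accept every candidate (score 1.0): recall 1 on any labeled set."""

    def score(self, masked: MaskedSentence) -> float:
        return 1.0


class NearestMethodClassifier:
    """Accept a candidate only if its gene is the nearest to the method.

    Among every gene matched in the sentence, the masked gene must be the
    one with the smallest character gap to the masked method's span; all
    other genes in the sentence score 0.
    """

    def __init__(self, index: TermIndex):
        self.index = index

    @staticmethod
    def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
        if a[1] <= b[0]:
            return b[0] - a[1]
        if b[1] <= a[0]:
            return a[0] - b[1]
        return 0

    def score(self, masked: MaskedSentence) -> float:
        cand = masked.provenance
        gene_spans = [
            (s, e)
            for s, e, kind, _ in self.index.find_matches(cand.sentence_text)
            if kind == "gene"
        ]
        if not gene_spans:
            return 0.0
        best = min(gene_spans, key=lambda sp: (self._gap(sp, cand.method_span), sp[0]))
        return 1.0 if best == cand.gene_span else 0.0


@dataclass(frozen=True)
class ExperimentMention:
    """An accepted gene–experiment relation with its document position."""

    article_id: str
    year: int
    sentence_index: int
    order_index: int
    gene_symbol: str
    method_name: str
    relation_score: float


def classify_relation(masked: MaskedSentence, classifier: RelationClassifier) -> float:
    """Score one masked candidate, attaching provenance to any failure."""
    try:
        return float(classifier.score(masked))
    except Exception as exc:
        cand = masked.provenance
        raise RuntimeError(
            f"relation classifier failed on article {cand.article_id!r} "
            f"sentence {cand.sentence_index} ({cand.gene_symbol}, {cand.method_name})"
        ) from exc


def extract_experiments(
    articles: Iterable[tuple[str, int, list[str]]],
    index: TermIndex,
    classifier: RelationClassifier,
    threshold: float = 0.5,
) -> list[ExperimentMention]:
    """Run candidate generation + relation classification over a corpus.

    ``articles`` yields (article_id, year, sentences) with sentences in
    document order.  Mentions scoring at or above ``threshold`` are kept,
    ordered per article by (sentence index, gene position, method position)
    and numbered 0, 1, 2, ... within each article.
    """
    mentions: list[ExperimentMention] = []
    for article_id, year, sentences in articles:
        accepted: list[tuple[tuple[int, int, int], CandidatePair, float]] = []
        for si, sentence in enumerate(sentences):
            if not sentence:
                continue
            for cand in find_candidates(sentence, index, article_id, year, si):
                score = classify_relation(mask_candidate(cand), classifier)
                if score >= threshold:
                    accepted.append(((si, cand.gene_span[0], cand.method_span[0]), cand, score))
        accepted.sort(key=lambda it: it[0])
        for order, (_, cand, score) in enumerate(accepted):
            mentions.append(
                ExperimentMention(
                    article_id=article_id,
                    year=year,
                    sentence_index=cand.sentence_index,
                    order_index=order,
                    gene_symbol=cand.gene_symbol,
                    method_name=cand.method_name,
                    relation_score=score,
                )
            )
    return mentions


_SENTENCE_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9\[])")


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitter on [.!?] + space + capital heuristic.

    Deliberately simple and pluggable: extraction accepts any pre-split
    sentence list, so a stronger segmenter can be swapped in upstream.
    """
    return [s for s in (_s.strip() for _s in _SENTENCE_RE.split(text)) if s]
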