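"""Consecutive-experiment gene pairs: construction, splits, negatives.

The supervised unit of the recommender is the ordered tuple
(gene of experiment *i*, gene of experiment *i+1*) within one article's
result narrative.  Only different-gene pairs are kept by default: a manual
audit of consecutive experiment descriptions found that different-gene
adjacencies reflect genuinely sequential experiments far more reliably
(91.7%) than same-gene adjacencies (64.7%), which often re-describe a
single experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np

from .corpus import ExperimentMention


@dataclass(frozen=True)
class ExperimentPair:
    """Ordered (previous gene, next gene) tuple; label 1 = observed."""

    gene_prev: str
    gene_next: str
    article_id: str = ""
    year: int = 0
    label: int = 1

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.label == 1 and self.gene_prev == self.gene_next:
            raise ValueError("observed pairs must join two different genes")

    @property
    def tuple(self) -> tuple[str, str]:
        return (self.gene_prev, self.gene_next)


def build_pairs(
    mentions: Sequence[ExperimentMention], keep_same_gene: bool = False
) -> list[ExperimentPair]:
    """Adjacent-mention gene pairs per article; never across articles.

    ``mentions`` must be grouped by article and sorted by ``order_index``
    within each group.  Same-gene adjacencies are dropped unless
    ``keep_same_gene`` (in which case they carry label 0 semantics is NOT
    applied — they are returned as raw tuples for auditing only).
    """
    pairs: list[ExperimentPair] = []
    for article_id, group in groupby(mentions, key=lambda m: m.article_id):
        ms = list(group)
        if [m.order_index for m in ms] != sorted(m.order_index for m in ms):
            raise ValueError(f"mentions of article {article_id!r} are not sorted by order_index")
        for prev, nxt in zip(ms, ms[1:]):
            same = prev.gene_symbol == nxt.gene_symbol
            if same and not keep_same_gene:
                continue
            pairs.append(
                ExperimentPair(
                    gene_prev=prev.gene_symbol,
                    gene_next=nxt.gene_symbol,
                    article_id=article_id,
                    year=prev.year,
                    # same-gene adjacencies are audit material, never positives
                    label=0 if same else 1,
                )
            )
    return pairs


@dataclass
class SplitDataset:
    """Temporal train/validation/test partition of experiment pairs."""

    train: list[ExperimentPair]
    validation: list[ExperimentPair]
    test: list[ExperimentPair]
    boundaries: tuple[int, int, int]

    def __post_init__(self) -> None:
        sets = [
            {p.article_id for p in split} for split in (self.train, self.validation, self.test)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("splits share articles")


def temporal_split(
    pairs: Iterable[ExperimentPair],
    train_end_year: int = 2018,
    validation_year: int = 2019,
    test_start_year: int = 2020,
) -> SplitDataset:
    """Split by publication year: ≤train_end / ==validation / ≥test_start."""
    if not (train_end_year < validation_year < test_start_year):
        raise ValueError("split boundaries must be strictly increasing")
    train, validation, test = [], [], []
    for p in pairs:
        if p.year <= train_end_year:
            train.append(p)
        elif p.year == validation_year:
            validation.append(p)
        elif p.year >= test_start_year:
            test.append(p)
    return SplitDataset(train, validation, test, (train_end_year, validation_year, test_start_year))


def sample_negatives(
    positives: Sequence[ExperimentPair],
    universe: Sequence[str],
    ratio: int = 3,
    seed: int = 0,
    collision_scope: str = "global",
) -> list[ExperimentPair]:
    """Corrupt the second gene of each positive to make negative tuples.

    For each positive, ``ratio`` negatives keep ``gene_prev`` and replace
    ``gene_next`` with a uniform draw from ``universe``; draws colliding
    with any observed positive tuple, with ``gene_prev`` itself, or with an
    earlier draw for the same positive are rejected and redrawn.
    Deterministic under a fixed seed.

    ``collision_scope`` is ``"global"`` (reject against the positive set of
    the whole input, the default) or ``"per_article"``.
    """
    if len(universe) <= 1:
        raise ValueError("universe must contain more than one gene")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if collision_scope not in ("global", "per_article"):
        raise ValueError(f"unknown collision scope {collision_scope!r}")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    global_pos = {p.tuple for p in positives}
    by_article: dict[str, set[tuple[str, str]]] = {}
    if collision_scope == "per_article":
        for p in positives:
            by_article.setdefault(p.article_id, set()).add(p.tuple)

    negatives: list[ExperimentPair] = []
    for pos in positives:
        forbidden_pos = global_pos if collision_scope == "global" else by_article[pos.article_id]
        legal = sum(
            1
            for g in universe
            if g != pos.gene_prev and (pos.gene_prev, g) not in forbidden_pos
        )
        if legal < ratio:
            raise ValueError(
                f"universe exhausted: only {legal} legal replacements for positive "
                f"({pos.gene_prev}, {pos.gene_next}), need {ratio}"
            )
        drawn: set[str] = set()
        while len(drawn) < ratio:
            g = universe[int(rng.integers(len(universe)))]
            if g == pos.gene_prev or g in drawn or (pos.gene_prev, g) in forbidden_pos:
                continue
            drawn.add(g)
            negatives.append(
                ExperimentPair(
                    gene_prev=pos.gene_prev,
                    gene_next=g,
                    article_id=pos.article_id,
                    year=pos.year,
                    label=0,
                )
            )
    return negatives


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with a percentile-bootstrap confidence interval."""

    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.proportion <= self.ci_high <= 1.0):
            raise ValueError("CI must bracket the proportion within [0, 1]")


def sequentiality_stats(
    numerator: int, denominator: int, n_boot: int = 10_000, seed: int = 0
) -> ProportionEstimate:
    """Proportion of audited adjacencies that were truly sequential.

    The point estimate is ``numerator / denominator``; the 95% CI is a
    percentile bootstrap (``n_boot`` resamples with replacement) over the
    ``denominator`` Bernoulli audit outcomes.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    prop = numerator / denominator
    rng = np.random.default_rng(seed)
    draws = rng.binomial(denominator, prop, size=n_boot) / denominator
    lo, hi = np.percentile(draws, [2.5, 97.5])
    lo = min(float(lo), prop)
    hi = max(float(hi), prop)
    return ProportionEstimate(numerator, denominator, prop, lo, hi, n_boot, seed)
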