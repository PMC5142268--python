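"""Phenotype consensus scoring.

Given a query phenotype (a set of ontology terms), every gene in the annotated
universe receives a symmetric semantic similarity score.  Consensus is then
the tendency of the candidate's mechanistically related genes to score higher
than the background of all other disease-annotated genes, quantified by a
one-sided Mann-Whitney U test (alternative: related scores stochastically
greater).

Two conventions matter and are fixed here:

* The candidate's own score is excluded from both groups by default (its known
  disease association must not confirm itself); a display-only candidate score
  is still reported.
* A related set whose members carry no phenotype annotations yields a
  *not-computable* outcome, a first-class result rather than an error — the
  validation "potential" metric counts exactly these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationCorpus
from .errors import EmptySetError
from .ontology import OntologyGraph
from .similarity import ICTable, best_match_matrix, score_universe

__all__ = [
    "ConsensusResult",
    "mann_whitney_one_sided_p",
    "consensus_test",
    "best_pathway_consensus",
    "background_quantiles",
]

#: Largest pooled sample size for which the exact permutation null is used.
EXACT_LIMIT = 12

#: Above EXACT_LIMIT, tie-free pooled samples up to this size still use the
#: exact rank-sum distribution (dynamic programming); the plain normal
#: approximation is only engaged where it is accurate.  At pooled size 12 the
#: continuity-corrected normal deviates from the exact null by up to ~0.06
#: for very unbalanced splits, so switching straight to it would make the
#: p-value jump across the enumeration boundary.
TIE_FREE_EXACT_LIMIT = 40

#: Background quantile probabilities reported by default.
DEFAULT_QUANTILES = (0.50, 0.75, 0.95)


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of one consensus test.

    ``p_value`` is ``None`` and ``n_related_scored`` is 0 for the
    not-computable outcome (no related gene carries annotations).
    """

    candidate: str
    source: str
    related_scores: dict[str, float]
    background_scores: dict[str, float]
    p_value: float | None
    n_related_scored: int
    quantiles: dict[float, float]
    best_matches: pd.DataFrame | None
    candidate_score: float | None = None
    n_sources_tested: int = 1

    @property
    def computable(self) -> bool:
        return self.p_value is not None


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided p by enumerating all assignments of pooled values.

    p = fraction of C(n, |x|) group assignments whose rank-sum for the first
    group is >= the observed rank-sum (mid-ranks shared across assignments,
    so ties are handled exactly).
    """
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    nx = len(x)
    observed = ranks[:nx].sum()
    total = 0
    hits = 0
    # enumerate index subsets; rank multiset is fixed so only the assignment varies
    for subset in combinations(range(len(pooled)), nx):
        total += 1
        if ranks[list(subset)].sum() >= observed - 1e-9:
            hits += 1
    return hits / total


def _large_sample_p(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided p beyond the enumeration limit.

    Tie-free pooled samples up to :data:`TIE_FREE_EXACT_LIMIT` use the exact
    null distribution of the U statistic; everything else uses the normal
    approximation with mid-rank ties, tie-corrected variance and continuity
    correction."""
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(pooled) <= TIE_FREE_EXACT_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def mann_whitney_one_sided_p(
    x: Iterable[float], y: Iterable[float], exact_limit: int = EXACT_LIMIT
) -> float:
    """One-sided Mann-Whitney p-value for "x stochastically greater than y".

    Exact permutation enumeration when the pooled size is <= *exact_limit*
    (default 12); otherwise the tie-corrected normal approximation with
    continuity correction.  Returns a value in (0, 1].
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise EmptySetError("Mann-Whitney test requires two nonempty samples")
    if len(x) + len(y) <= exact_limit:
        return _exact_p(x, y)
    return min(1.0, _large_sample_p(x, y))


def background_quantiles(
    background_scores: Iterable[float] | Mapping[str, float],
    probabilities: Sequence[float] = DEFAULT_QUANTILES,
) -> dict[float, float]:
    """Empirical quantiles of the background score distribution.

    Linear interpolation between order statistics (numpy's default
    ``linear`` convention).
    """
    if isinstance(background_scores, Mapping):
        background_scores = background_scores.values()
    values = np.asarray(list(background_scores), dtype=float)
    if values.size == 0:
        raise EmptySetError("background score collection is empty")
    return {
        float(p): float(np.quantile(values, p, method="linear"))
        for p in probabilities
    }


def consensus_test(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    ic_table: ICTable,
    query_terms: Iterable[str],
    related: Iterable[str],
    candidate: str,
    source: str = "custom",
    *,
    include_candidate: bool = False,
    universe_scores: Mapping[str, float] | None = None,
    with_best_matches: bool = True,
    quantile_probs: Sequence[float] = DEFAULT_QUANTILES,
) -> ConsensusResult:
    """Run the consensus test for one candidate and one related gene set.

    Every universe gene is scored against the query; related genes are
    intersected with the universe, the candidate is removed from both groups
    (unless ``include_candidate``), and the one-sided Mann-Whitney p compares
    related against background scores.  ``universe_scores`` may carry
    precomputed scores for this (corpus, query) pair to avoid rescoring when
    many related sets are tested against the same query.
    """
    query = set(query_terms)
    if not query:
        raise EmptySetError("query term set is empty")
    related = set(related)
    if not related:
        raise EmptySetError("related gene set is empty")

    if universe_scores is None:
        universe_scores = score_universe(ic_table, graph, corpus, query)

    candidate_score = universe_scores.get(candidate)
    scored_related = (related & corpus.universe) - {candidate}
    if include_candidate and candidate in corpus.universe:
        scored_related |= {candidate} & related

    related_scores = {g: universe_scores[g] for g in sorted(scored_related)}
    background = corpus.universe - scored_related
    if not include_candidate:
        background -= {candidate}
    background_scores = {g: universe_scores[g] for g in sorted(background)}

    quantiles = (
        background_quantiles(background_scores, quantile_probs)
        if background_scores
        else {}
    )

    if not related_scores or not background_scores:
        return ConsensusResult(
            candidate=candidate,
            source=source,
            related_scores=related_scores,
            background_scores=background_scores,
            p_value=None,
            n_related_scored=len(related_scores),
            quantiles=quantiles,
            best_matches=None,
            candidate_score=candidate_score,
        )

    p = mann_whitney_one_sided_p(related_scores.values(), background_scores.values())
    best = (
        best_match_matrix(
            ic_table, graph, sorted(query), sorted(related_scores), corpus
        )
        if with_best_matches
        else None
    )
    return ConsensusResult(
        candidate=candidate,
        source=source,
        related_scores=related_scores,
        background_scores=background_scores,
        p_value=p,
        n_related_scored=len(related_scores),
        quantiles=quantiles,
        best_matches=best,
        candidate_score=candidate_score,
    )


def best_pathway_consensus(results: Sequence[ConsensusResult]) -> ConsensusResult:
    """Select the most significant computable result among several sources.

    Returns the result with minimal p-value (no multiple-testing correction),
    annotated with the number of sources tested; ties break toward larger
    ``n_related_scored``, then lexicographic source.  If every result is
    not-computable, a not-computable result is returned.
    """
    if not results:
        raise EmptySetError("no consensus results to select from")
    computable = [r for r in results if r.computable]
    pool = computable or list(results)
    best = min(
        pool, key=lambda r: (r.p_value if r.computable else math.inf,
                             -r.n_related_scored, r.source)
    )
    return ConsensusResult(
        candidate=best.candidate,
        source=best.source,
        related_scores=best.related_scores,
        background_scores=best.background_scores,
        p_value=best.p_value,
        n_related_scored=best.n_related_scored,
        quantiles=best.quantiles,
        best_matches=best.best_matches,
        candidate_score=best.candidate_score,
        n_sources_tested=len(results),
    )
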