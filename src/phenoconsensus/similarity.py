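"""Information content and Resnik-style semantic similarity over term sets.

For each ontology term ``p`` the information content is

    IC_p = -ln(|p| / |Omega|)

where ``|p|`` counts the universe genes annotated to the term or any of its
descendants (annotations propagate up the ``is_a`` DAG) and ``|Omega|`` is the
size of the annotated-gene universe.  The similarity of two terms is the IC of
their most informative common ancestor (MICA); two term sets are compared by
averaging best matches in each direction and averaging the two directed
scores (symmetric best-match-average similarity).

All scores are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .annotations import AnnotationCorpus
from .errors import AbsentGeneError, EmptyCorpusError, EmptySetError, UnknownTermError
from .ontology import OntologyGraph, ancestors_of

__all__ = [
    "ICTable",
    "compute_ic",
    "term_similarity",
    "directed_set_similarity",
    "symmetric_similarity",
    "best_match_matrix",
    "score_universe",
]


@dataclass
class ICTable:
    """Per-term information content derived from propagated gene counts.

    Terms annotated by no universe gene (directly or via a descendant) carry
    no IC entry and are skipped as MICA candidates.
    """

    ic: dict[str, float]
    annotated_gene_count: dict[str, int]
    omega: int
    _pair_cache: dict[frozenset, float] = field(
        default_factory=dict, repr=False, compare=False
    )

    def max_ic(self) -> float:
        return max(self.ic.values(), default=0.0)


def compute_ic(graph: OntologyGraph, corpus: AnnotationCorpus) -> ICTable:
    """Compute the IC table for *corpus* over *graph*.

    Each universe gene contributes once to every ancestor of every term it is
    annotated with; ``ic = -ln(count / omega)`` for terms with count > 0.
    """
    omega = corpus.omega
    if omega == 0:
        raise EmptyCorpusError("cannot compute information content: empty universe")
    counts: dict[str, int] = {}
    for gene in corpus.universe:
        propagated: set[str] = set()
        for term in corpus.gene_terms[gene]:
            propagated |= ancestors_of(graph, term)
        for term in propagated:
            counts[term] = counts.get(term, 0) + 1
    ic = {t: -math.log(c / omega) for t, c in counts.items()}
    return ICTable(ic=ic, annotated_gene_count=counts, omega=omega)


def term_similarity(
    table: ICTable, graph: OntologyGraph, t1: str, t2: str
) -> float:
    """Resnik similarity: IC of the most informative common ancestor.

    IC-less common ancestors (no annotated gene) are skipped; if no IC-bearing
    common ancestor exists the similarity is 0.
    """
    key = frozenset((t1, t2))
    hit = table._pair_cache.get(key)
    if hit is not None:
        return hit
    common = ancestors_of(graph, t1) & ancestors_of(graph, t2)
    ic = table.ic
    value = max((ic[a] for a in common if a in ic), default=0.0)
    table._pair_cache[key] = value
    return value


def directed_set_similarity(
    table: ICTable, graph: OntologyGraph, query: Iterable[str], disease: Iterable[str]
) -> float:
    """Best-match average of *query* terms against *disease* terms.

    sim(Q -> D) = (1/|Q|) * sum over t1 in Q of max over t2 in D of SS(t1, t2).
    Term collections are deduplicated before averaging.
    """
    q = set(query)
    d = set(disease)
    if not q or not d:
        raise EmptySetError("directed similarity requires nonempty term sets")
    return sum(
        max(term_similarity(table, graph, t1, t2) for t2 in d) for t1 in q
    ) / len(q)


def symmetric_similarity(
    table: ICTable, graph: OntologyGraph, query: Iterable[str], disease: Iterable[str]
) -> float:
    """Average of the two directed best-match similarities."""
    q = set(query)
    d = set(disease)
    return 0.5 * (
        directed_set_similarity(table, graph, q, d)
        + directed_set_similarity(table, graph, d, q)
    )


def best_match_matrix(
    table: ICTable,
    graph: OntologyGraph,
    query_terms: Sequence[str],
    genes: Sequence[str],
    corpus: AnnotationCorpus,
) -> pd.DataFrame:
    """Best term similarity between each query term (rows) and gene (columns).

    Entry (t, g) = max over t2 in the gene's phenotype profile of SS(t, t2).
    The column mean times |Q| recovers the directed set similarity Q -> gene.
    """
    if not query_terms:
        raise EmptySetError("query term list is empty")
    for g in genes:
        if g not in corpus.universe:
            raise AbsentGeneError(g)
    data = {
        g: [
            max(term_similarity(table, graph, t, t2) for t2 in corpus.gene_terms[g])
            for t in query_terms
        ]
        for g in genes
    }
    return pd.DataFrame(data, index=list(query_terms), columns=list(genes))


def score_universe(
    table: ICTable,
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    query_terms: Iterable[str],
) -> dict[str, float]:
    """Symmetric similarity of the query against every universe gene.

    Computed efficiently by first scoring each query term against every term
    appearing in any gene profile, then folding per gene; equivalent to
    calling :func:`symmetric_similarity` gene by gene.
    """
    q = set(query_terms)
    if not q:
        raise EmptySetError("query term set is empty")
    corpus_terms: set[str] = set()
    for terms in corpus.gene_terms.values():
        corpus_terms |= terms
    sim = {
        t: {t2: term_similarity(table, graph, t, t2) for t2 in corpus_terms}
        for t in q
    }
    scores: dict[str, float] = {}
    for gene in corpus.universe:
        terms = corpus.gene_terms[gene]
        q_to_d = sum(max(sim[t][t2] for t2 in terms) for t in q) / len(q)
        d_to_q = sum(max(sim[t][t2] for t in q) for t2 in terms) / len(terms)
        scores[gene] = 0.5 * (q_to_d + d_to_q)
    return scores
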