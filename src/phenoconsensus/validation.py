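"""Leave-one-out rediscovery validation and performance metrics.

For each known gene-disease association the true gene's phenotype annotations
are removed from the corpus, information content is recomputed on the masked
corpus, and the consensus test is run for the true candidate and for a set of
randomly sampled negative-control genes not linked to the disease.  Three
metrics summarize a batch of such records:

* **potential** — fraction of associations for which a p-value is computable
  (the candidate had at least one annotated related gene);
* **AUC** — area under the ROC curve over pooled candidate/negative scores
  (score = -p, mid-rank ties);
* **median rank percentile** — median position of the candidate's p-value
  among itself plus its computable negatives.

Per-association random streams are derived from (master seed, association
index over the sorted association list), so results are identical across
evaluation orders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotations import AnnotationCorpus, remove_gene_annotations
from .consensus import ConsensusResult, best_pathway_consensus, consensus_test
from .errors import DegenerateInputError, EmptySetError
from .mechanisms import Network, PathwayCollection, candidate_pathways, neighbor_genes
from .ontology import OntologyGraph
from .similarity import ICTable, compute_ic, score_universe

__all__ = [
    "RelatedGeneResource",
    "NetworkNeighborResource",
    "PathwayResource",
    "CustomSetResource",
    "ValidationRecord",
    "PerformanceSummary",
    "loo_evaluate",
    "evaluate_associations",
    "roc_auc",
    "performance_summary",
    "combine_min_p",
    "records_to_tsv",
]


class RelatedGeneResource:
    """Abstract source of mechanistically related gene sets.

    Subclasses return, for a candidate gene, a list of labelled related sets
    (one per pathway, or a single neighbor set).  The consensus test is run
    per set and the most significant computable result is reported.
    """

    label: str = "resource"

    def related_sets(self, gene: str) -> list[tuple[str, frozenset[str]]]:
        raise NotImplementedError


class NetworkNeighborResource(RelatedGeneResource):
    """Related genes = interaction neighbors passing a confidence threshold."""

    def __init__(self, network: Network, direction: str = "all", min_score: float = 0.5,
                 label: str | None = None):
        self.network = network
        self.direction = direction
        self.min_score = min_score
        self.label = label or f"network:{direction}:>={min_score:g}"

    def related_sets(self, gene: str) -> list[tuple[str, frozenset[str]]]:
        neighbors = neighbor_genes(self.network, gene, self.direction, self.min_score)
        if not neighbors:
            return []
        return [(self.label, neighbors)]


class PathwayResource(RelatedGeneResource):
    """Related genes = co-members of each pathway containing the candidate."""

    def __init__(self, collection: PathwayCollection, label: str = "pathways"):
        self.collection = collection
        self.label = label

    def related_sets(self, gene: str) -> list[tuple[str, frozenset[str]]]:
        return [
            (f"{self.label}:{ident}", members)
            for ident, members in candidate_pathways(self.collection, gene)
            if members
        ]


class CustomSetResource(RelatedGeneResource):
    """Related genes supplied directly (e.g. gene-family members)."""

    def __init__(self, genes: Iterable[str], label: str = "custom"):
        self.genes = frozenset(genes)
        self.label = label

    def related_sets(self, gene: str) -> list[tuple[str, frozenset[str]]]:
        members = self.genes - {gene}
        return [(self.label, members)] if members else []


@dataclass(frozen=True)
class ValidationRecord:
    """Leave-one-out outcome for one gene-disease association."""

    association: tuple[str, str]
    resource_label: str
    candidate_p: float | None
    negative_ps: tuple[tuple[str, float | None], ...]
    rank_percentile: float | None
    seed: int

    @property
    def computable(self) -> bool:
        return self.candidate_p is not None


@dataclass(frozen=True)
class PerformanceSummary:
    n_associations: int
    potential: float
    auc: float | None
    median_rank_percentile: float | None


def _rank_percentile(
    candidate_p: float | None, negative_ps: Sequence[tuple[str, float | None]]
) -> float | None:
    """Mid-rank of the candidate's p among itself plus computable negatives,
    normalized by 1 + number of computable negatives (smaller is better)."""
    if candidate_p is None:
        return None
    neg = [p for _, p in negative_ps if p is not None]
    pool = np.asarray([candidate_p] + neg, dtype=float)
    ranks = stats.rankdata(pool, method="average")
    return float(ranks[0] / len(pool))


def _best_consensus_p(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    ic_table: ICTable,
    query_terms: frozenset[str],
    resource: RelatedGeneResource,
    gene: str,
    universe_scores: Mapping[str, float],
) -> float | None:
    sets = resource.related_sets(gene)
    if not sets:
        return None
    results = [
        consensus_test(
            corpus, graph, ic_table, query_terms, members, gene, source=label,
            universe_scores=universe_scores, with_best_matches=False,
        )
        for label, members in sets
        if members
    ]
    if not results:
        return None
    best = best_pathway_consensus(results)
    return best.p_value


def loo_evaluate(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    resource: RelatedGeneResource,
    association: tuple[str, str],
    n_negatives: int = 100,
    seed: int = 0,
    *,
    recompute_ic: bool = True,
    ic_table: ICTable | None = None,
) -> ValidationRecord:
    """Evaluate one gene-disease association by leave-one-out rediscovery.

    The true gene's annotations are removed from the corpus; information
    content is recomputed on the masked corpus by default (``recompute_ic=
    False`` reuses a supplied global ``ic_table`` as a labelled
    approximation).  Negatives are sampled uniformly without replacement from
    the masked universe, excluding genes linked to the disease; only the true
    candidate's annotations are ever masked (negatives are excluded from both
    test groups regardless, so their own annotations cannot self-confirm).
    """
    gene, disease = association
    query_terms = corpus.disease_terms.get(disease)
    if not query_terms:
        raise EmptySetError(f"disease {disease!r} carries no phenotype terms")

    masked = remove_gene_annotations(corpus, gene)
    if recompute_ic or ic_table is None:
        table = compute_ic(graph, masked)
    else:
        table = ic_table

    disease_genes = corpus.genes_of_disease(disease)
    pool = sorted(masked.universe - disease_genes - {gene})
    k = min(n_negatives, len(pool))
    rng = np.random.default_rng([seed, _association_index(association)])
    negatives = sorted(rng.choice(pool, size=k, replace=False).tolist())

    universe_scores = score_universe(table, graph, masked, query_terms)
    candidate_p = _best_consensus_p(
        masked, graph, table, query_terms, resource, gene, universe_scores
    )
    negative_ps = tuple(
        (g, _best_consensus_p(masked, graph, table, query_terms, resource, g,
                              universe_scores))
        for g in negatives
    )
    return ValidationRecord(
        association=association,
        resource_label=resource.label,
        candidate_p=candidate_p,
        negative_ps=negative_ps,
        rank_percentile=_rank_percentile(candidate_p, negative_ps),
        seed=seed,
    )


def _association_index(association: tuple[str, str]) -> int:
    """Stable 31-bit stream index for an association, order-independent."""
    import zlib

    key = f"{association[0]}\t{association[1]}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def evaluate_associations(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    resource: RelatedGeneResource,
    associations: Iterable[tuple[str, str]],
    n_negatives: int = 100,
    seed: int = 0,
    **kwargs,
) -> list[ValidationRecord]:
    """Run :func:`loo_evaluate` for every association.

    Records are returned sorted by association, and each association's random
    stream depends only on (seed, association), so the output is independent
    of the input ordering.
    """
    records = [
        loo_evaluate(corpus, graph, resource, assoc, n_negatives, seed, **kwargs)
        for assoc in associations
    ]
    return sorted(records, key=lambda r: r.association)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC over positive-negative score pairs with 0.5 credit for ties.

    Equivalent to the Mann-Whitney U statistic normalized by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("AUC requires at least one positive and one negative")
    ranks = stats.rankdata(scores, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def performance_summary(records: Sequence[ValidationRecord]) -> PerformanceSummary:
    """Summarize a batch of leave-one-out records.

    AUC pools all candidate and negative p-values globally (score = -p,
    not-computable entries excluded); potential and the median rank percentile
    follow the definitions in the module docstring.
    """
    if not records:
        raise EmptySetError("no validation records")
    computable = [r for r in records if r.computable]
    potential = len(computable) / len(records)
    scores: list[float] = []
    labels: list[bool] = []
    for rec in records:
        if rec.candidate_p is not None:
            scores.append(-rec.candidate_p)
            labels.append(True)
        for _, p in rec.negative_ps:
            if p is not None:
                scores.append(-p)
                labels.append(False)
    auc = None
    if any(labels) and not all(labels):
        auc = roc_auc(scores, labels)
    ranks = [r.rank_percentile for r in computable if r.rank_percentile is not None]
    median_rank = float(np.median(ranks)) if ranks else None
    return PerformanceSummary(
        n_associations=len(records),
        potential=potential,
        auc=auc,
        median_rank_percentile=median_rank,
    )


def combine_min_p(
    a: Sequence[ValidationRecord], b: Sequence[ValidationRecord]
) -> list[ValidationRecord]:
    """Combine two resources' records per association by taking the minimum
    computable p-value for the candidate and for each negative gene.

    A combined value is not-computable only when both inputs are.  Rank
    percentiles are recomputed from the combined values.  Associations present
    in only one list pass through unchanged (outer alignment); an association
    present in neither is impossible by construction and simply absent.
    """
    by_assoc_a = {r.association: r for r in a}
    by_assoc_b = {r.association: r for r in b}
    combined: list[ValidationRecord] = []
    for assoc in sorted(set(by_assoc_a) | set(by_assoc_b)):
        ra, rb = by_assoc_a.get(assoc), by_assoc_b.get(assoc)
        if ra is None or rb is None:
            combined.append(ra or rb)
            continue
        cand = _min_p(ra.candidate_p, rb.candidate_p)
        neg_a = dict(ra.negative_ps)
        neg_b = dict(rb.negative_ps)
        negatives = tuple(
            (g, _min_p(neg_a.get(g), neg_b.get(g)))
            for g in sorted(set(neg_a) | set(neg_b))
        )
        combined.append(
            ValidationRecord(
                association=assoc,
                resource_label=f"min({ra.resource_label},{rb.resource_label})",
                candidate_p=cand,
                negative_ps=negatives,
                rank_percentile=_rank_percentile(cand, negatives),
                seed=ra.seed,
            )
        )
    return combined


def _min_p(pa: float | None, pb: float | None) -> float | None:
    values = [p for p in (pa, pb) if p is not None]
    return min(values) if values else None


def records_to_tsv(records: Sequence[ValidationRecord]) -> str:
    """Serialize records deterministically (sorted by association, fixed
    float formatting) so identical inputs give byte-identical output."""
    lines = [
        "gene\tdisease\tresource\tcandidate_p\trank_percentile\tn_negatives"
        "\tn_computable_negatives\tnegative_ps"
    ]
    for rec in sorted(records, key=lambda r: r.association):
        gene, disease = rec.association
        neg = ";".join(
            f"{g}={_fmt(p)}" for g, p in sorted(rec.negative_ps)
        )
        n_comp = sum(1 for _, p in rec.negative_ps if p is not None)
        lines.append(
            "\t".join(
                [
                    gene,
                    disease,
                    rec.resource_label,
                    _fmt(rec.candidate_p),
                    _fmt(rec.rank_percentile),
                    str(len(rec.negative_ps)),
                    str(n_comp),
                    neg,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _fmt(p: float | None) -> str:
    return "NA" if p is None else format(p, ".12g")
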