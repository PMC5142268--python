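import dataclasses

import numpy as np
import pytest

import _oracles as oracle
from phenoconsensus.errors import DegenerateInputError
from phenoconsensus.synthetic import PlantedBenchmarkConfig, planted_benchmark
from phenoconsensus.validation import (
    NetworkNeighborResource,
    ValidationRecord,
    combine_min_p,
    evaluate_associations,
    loo_evaluate,
    performance_summary,
    records_to_tsv,
    roc_auc,
)


@pytest.fixture(scope="module")
def small_benchmark():
    cfg = PlantedBenchmarkConfig(
        depth=4, branching=3, n_genes=80, n_diseases=80, module_size=10,
        effect=0.8, p_within=0.6, p_between=0.03, seed=21,
    )
    return planted_benchmark(cfg)


def test_roc_auc_examples():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    # ties get half credit: pairs (0.8,0.5)=1, (0.8,0.2)=1, (0.5,0.5)=0.5, (0.5,0.2)=1
    assert roc_auc([0.8, 0.5, 0.5, 0.2], [1, 1, 0, 0]) == pytest.approx(0.875)
    with pytest.raises(DegenerateInputError):
        roc_auc([1.0, 2.0], [1, 1])


def test_roc_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        scores = rng.integers(0, 6, size=30).astype(float)
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            continue
        assert roc_auc(scores, labels) == pytest.approx(
            oracle.brute_auc(scores, labels), abs=1e-12
        )


def test_loo_evaluate_record_shape(small_benchmark):
    corpus, graph, network, associations = small_benchmark
    resource = NetworkNeighborResource(network)
    rec = loo_evaluate(corpus, graph, resource, associations[0], n_negatives=15, seed=9)
    gene, disease = rec.association
    negatives = [g for g, _ in rec.negative_ps]
    assert gene not in negatives
    assert len(set(negatives)) == len(negatives) == 15
    disease_genes = corpus.genes_of_disease(disease)
    assert not disease_genes & set(negatives)
    if rec.computable:
        pool = [p for _, p in rec.negative_ps if p is not None]
        assert 0 < rec.rank_percentile <= 1
        assert rec.rank_percentile <= 1.0
        better = sum(1 for p in pool if p < rec.candidate_p)
        assert rec.rank_percentile >= (better + 1) / (len(pool) + 1) - 1e-12


def test_loo_best_rank_percentile():
    rec = ValidationRecord(
        association=("G", "D"), resource_label="r",
        candidate_p=1e-6,
        negative_ps=tuple((f"N{i}", 0.5) for i in range(100)),
        rank_percentile=None, seed=0,
    )
    from phenoconsensus.validation import _rank_percentile

    assert _rank_percentile(rec.candidate_p, rec.negative_ps) == pytest.approx(1 / 101)


def test_loo_determinism_and_order_independence(small_benchmark):
    corpus, graph, network, associations = small_benchmark
    resource = NetworkNeighborResource(network)
    subset = associations[:5]
    a = evaluate_associations(corpus, graph, resource, subset, n_negatives=10, seed=3)
    b = evaluate_associations(corpus, graph, resource, subset[::-1], n_negatives=10, seed=3)
    assert records_to_tsv(a) == records_to_tsv(b)
    c = evaluate_associations(corpus, graph, resource, subset, n_negatives=10, seed=4)
    assert records_to_tsv(a) != records_to_tsv(c)  # seed actually matters


def _rec(assoc, cand, negs, label="r"):
    from phenoconsensus.validation import _rank_percentile

    negs = tuple(negs)
    return ValidationRecord(
        association=assoc, resource_label=label, candidate_p=cand,
        negative_ps=negs, rank_percentile=_rank_percentile(cand, negs), seed=0,
    )


def test_combine_min_p_rules():
    a = [
        _rec(("G1", "D1"), 0.03, [("N1", 0.2), ("N2", None)]),
        _rec(("G2", "D2"), 0.2, [("N1", 0.5)]),
        _rec(("G3", "D3"), None, [("N1", None)]),
    ]
    b = [
        _rec(("G1", "D1"), None, [("N1", 0.1), ("N2", 0.4)]),
        _rec(("G2", "D2"), 0.05, [("N1", 0.6)]),
        _rec(("G3", "D3"), None, [("N1", None)]),
    ]
    combined = combine_min_p(a, b)
    by = {r.association: r for r in combined}
    assert by[("G1", "D1")].candidate_p == 0.03        # one side not-computable
    assert by[("G2", "D2")].candidate_p == 0.05        # min of the two
    assert by[("G3", "D3")].candidate_p is None        # both not-computable
    assert dict(by[("G1", "D1")].negative_ps) == {"N1": 0.1, "N2": 0.4}
    # combined potential never drops below either input's
    pa = performance_summary(a).potential
    pb = performance_summary(b).potential
    pc = performance_summary(combined).potential
    assert pc >= max(pa, pb)


def test_performance_summary_metrics():
    records = [
        _rec(("G1", "D1"), 0.01, [("N1", 0.3), ("N2", 0.6)]),
        _rec(("G2", "D2"), 0.14, [("N1", 0.5), ("N2", 0.9)]),
        _rec(("G3", "D3"), None, [("N1", 0.2)]),
    ]
    s = performance_summary(records)
    assert s.n_associations == 3
    assert s.potential == pytest.approx(2 / 3)
    assert s.auc == 1.0  # both candidates beat every negative
    assert s.median_rank_percentile == pytest.approx((1 / 3 + 1 / 3) / 2)


def test_rank_percentile_improves_with_effect():
    """Planted effect size should monotonically improve the candidate's
    median rank percentile (Monte-Carlo, coarse)."""
    medians = []
    for effect in (0.0, 0.4, 0.8):
        cfg = PlantedBenchmarkConfig(
            depth=4, branching=3, n_genes=100, n_diseases=100, module_size=20,
            effect=effect, p_within=0.5, p_between=0.03, seed=17,
        )
        corpus, graph, network, associations = planted_benchmark(cfg)
        resource = NetworkNeighborResource(network)
        records = evaluate_associations(
            corpus, graph, resource, associations, n_negatives=15, seed=2
        )
        medians.append(performance_summary(records).median_rank_percentile)
    assert medians[2] <= medians[1] <= medians[0] + 0.15
    assert medians[2] < medians[0]
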