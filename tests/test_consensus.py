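import numpy as np
import pytest

import _oracles as oracle
from phenoconsensus.annotations import build_corpus
from phenoconsensus.consensus import (
    background_quantiles,
    best_pathway_consensus,
    consensus_test,
    mann_whitney_one_sided_p,
)
from phenoconsensus.errors import EmptySetError
from phenoconsensus.similarity import compute_ic, score_universe


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([5, 6, 7], [1, 2, 3, 4], 1 / 35),  # top three ranks: 1 of C(7,3) assignments
        ([1], [2], 1.0),                    # observed rank-sum is the minimum
        ([2], [2], 1.0),                    # all permutations tie
    ],
)
def test_mwu_exact_examples(x, y, expected):
    assert mann_whitney_one_sided_p(x, y) == pytest.approx(expected, abs=1e-12)


def test_mwu_requires_nonempty_samples():
    with pytest.raises(EmptySetError):
        mann_whitney_one_sided_p([], [1.0])


def test_mwu_exact_matches_bruteforce_with_ties():
    rng = np.random.default_rng(11)
    for _ in range(40):
        nx = int(rng.integers(1, 5))
        ny = int(rng.integers(1, 9 - nx))
        x = rng.integers(0, 4, size=nx).astype(float)
        y = rng.integers(0, 4, size=ny).astype(float)
        assert mann_whitney_one_sided_p(x, y) == pytest.approx(
            oracle.brute_mwu_greater_p(list(x), list(y)), abs=1e-12
        )


def test_mwu_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    x = rng.normal(0.5, 1, size=30)
    y = rng.normal(0.0, 1, size=200)
    p0 = mann_whitney_one_sided_p(x, y)
    p1 = mann_whitney_one_sided_p(np.exp(x), np.exp(y))
    p2 = mann_whitney_one_sided_p(3 * x + 7, 3 * y + 7)
    assert p0 == pytest.approx(p1, abs=1e-12)
    assert p0 == pytest.approx(p2, abs=1e-12)


def _five_gene_setting():
    """Five-gene universe where the related pair holds the top two scores."""
    graph_corpus = build_corpus(
        {
            "dA": frozenset({"B"}),
            "dB": frozenset({"B", "C"}),
            "dC": frozenset({"C"}),
            "dD": frozenset({"D"}),
            "dE": frozenset({"D"}),
        },
        {
            "Ga": frozenset({"dA"}),
            "Gb": frozenset({"dB"}),
            "Gc": frozenset({"dC"}),
            "Gd": frozenset({"dD"}),
            "Ge": frozenset({"dE"}),
        },
    )
    return graph_corpus


def test_consensus_test_exact_p(diamond_graph):
    corpus = _five_gene_setting()
    table = compute_ic(diamond_graph, corpus)
    query = {"B"}
    scores = score_universe(table, diamond_graph, corpus, query)
    related = {"Ga", "Gb"}
    top_two = sorted(scores, key=scores.get, reverse=True)[:2]
    assert set(top_two) == related
    res = consensus_test(
        corpus, diamond_graph, table, query, related, candidate="NONE"
    )
    # related genes hold the top two of five ranks: p = 1 / C(5,2)
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    assert res.n_related_scored == 2
    assert set(res.related_scores) | set(res.background_scores) == corpus.universe
    assert not set(res.related_scores) & set(res.background_scores)


def test_consensus_candidate_excluded_by_default(diamond_graph):
    corpus = _five_gene_setting()
    table = compute_ic(diamond_graph, corpus)
    res = consensus_test(
        corpus, diamond_graph, table, {"B"}, {"Ga", "Gb"}, candidate="Ga"
    )
    assert "Ga" not in res.related_scores
    assert "Ga" not in res.background_scores
    assert res.candidate_score is not None  # display-only score survives
    inc = consensus_test(
        corpus, diamond_graph, table, {"B"}, {"Ga", "Gb"}, candidate="Ga",
        include_candidate=True,
    )
    assert "Ga" in inc.related_scores


def test_consensus_not_computable_when_related_unannotated(diamond_graph):
    corpus = _five_gene_setting()
    table = compute_ic(diamond_graph, corpus)
    res = consensus_test(
        corpus, diamond_graph, table, {"B"}, {"UNKNOWN1", "UNKNOWN2"},
        candidate="NONE",
    )
    assert not res.computable
    assert res.p_value is None
    assert res.n_related_scored == 0


def test_best_pathway_consensus_selection(diamond_graph):
    corpus = _five_gene_setting()
    table = compute_ic(diamond_graph, corpus)

    def run(related, source):
        return consensus_test(
            corpus, diamond_graph, table, {"B"}, related, "NONE", source=source
        )

    nc = run({"UNKNOWN"}, "s0")
    r1 = run({"Ga", "Gb"}, "s1")   # p = 0.1
    r2 = run({"Gd"}, "s2")         # low scores -> larger p
    assert r2.p_value > r1.p_value
    best = best_pathway_consensus([nc, r2, r1])
    assert best.source == "s1" and best.n_sources_tested == 3
    only = best_pathway_consensus([r2])
    assert only.source == "s2" and only.n_sources_tested == 1
    none = best_pathway_consensus([nc])
    assert not none.computable


def test_background_quantiles():
    q = background_quantiles([0, 1, 2, 3, 4], [0.5, 0.0, 1.0])
    assert q[0.5] == 2.0
    assert q[0.0] == 0.0
    assert q[1.0] == 4.0
    with pytest.raises(EmptySetError):
        background_quantiles([])


def test_added_gene_leaves_other_scores_unchanged_under_frozen_ic(diamond_graph):
    """With the information-content table frozen, adding a gene to the corpus
    leaves every other gene's similarity score bitwise unchanged (and with
    recomputed IC the ranking is still preserved)."""
    corpus = _five_gene_setting()
    table = compute_ic(diamond_graph, corpus)
    scores = score_universe(table, diamond_graph, corpus, {"B"})
    bigger = build_corpus(
        dict(corpus.disease_terms, dX=frozenset({"D"})),
        dict(corpus.gene_diseases, Gx=frozenset({"dX"})),
    )
    frozen = score_universe(table, diamond_graph, bigger, {"B"})
    for g in corpus.universe:
        assert frozen[g] == scores[g]
    table2 = compute_ic(diamond_graph, bigger)
    scores2 = score_universe(table2, diamond_graph, bigger, {"B"})
    assert sorted(corpus.universe, key=scores.get) == sorted(
        corpus.universe, key=lambda g: scores2[g]
    )
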