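"""Synthetic fixtures: toy ontologies, planted-consensus corpora and modular
networks.

The planted benchmark emulates the statistical structure the consensus method
assumes: a module of mechanistically related genes whose diseases share
phenotype terms drawn from one designated ontology subtree, embedded in a
background of genes whose diseases sample terms uniformly.  ``effect``
controls the fraction of a module disease's terms that come from the planted
subtree — 0 gives a null corpus with no dependence between module membership
and phenotype, 1 confines module diseases entirely to the subtree.

Generators are deterministic given their seed, and every fixture can be
serialized to the standard flat formats (OBO, annotation TSV, gene-disease
TSV, edge-list TSV, GMT) so the real parsers are exercised by round-trip
tests rather than bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotations import AnnotationCorpus, build_corpus
from .mechanisms import Network
from .ontology import OntologyGraph, ancestors_of

__all__ = [
    "PlantedBenchmarkConfig",
    "make_toy_ontology",
    "make_synthetic_corpus",
    "make_synthetic_network",
    "planted_benchmark",
    "write_obo",
    "write_disease_annotations",
    "write_gene_disease_links",
    "write_network",
    "write_gmt",
]


@dataclass(frozen=True)
class PlantedBenchmarkConfig:
    """Parameters of the planted-consensus benchmark.

    Defaults describe a small but non-trivial study: a 200-gene disease corpus
    over a depth-5 binary-ish ontology, one 20-gene module with a strong
    phenotype effect, and a sparse background network with a dense module.
    """

    depth: int = 5
    branching: int = 3
    n_genes: int = 200
    n_diseases: int = 200
    module_size: int = 20
    effect: float = 0.8
    terms_per_disease: tuple[int, int] = (3, 6)
    p_within: float = 0.5
    p_between: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")


def make_toy_ontology(
    depth: int, branching: int, seed: int = 0, extra_edge_prob: float = 0.0
) -> OntologyGraph:
    """Complete rooted tree ontology of given depth and branching factor.

    Contains sum over k of branching^k terms.  With ``extra_edge_prob`` > 0,
    random additional is_a edges are added from deeper terms to shallower
    non-ancestor terms, creating diamonds while preserving acyclicity.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    terms: list[str] = []
    parents: dict[str, set[str]] = {}
    level_of: dict[str, int] = {}

    def tid(i: int) -> str:
        return f"TT:{i:07d}"

    counter = 0
    root = tid(counter)
    counter += 1
    terms.append(root)
    parents[root] = set()
    level_of[root] = 0
    frontier = [root]
    for level in range(1, depth + 1):
        nxt = []
        for parent in frontier:
            for _ in range(branching):
                t = tid(counter)
                counter += 1
                terms.append(t)
                parents[t] = {parent}
                level_of[t] = level
                nxt.append(t)
        frontier = nxt

    if extra_edge_prob > 0:
        by_level: dict[int, list[str]] = {}
        for t, lv in level_of.items():
            by_level.setdefault(lv, []).append(t)
        graph_tmp = OntologyGraph(
            terms=set(terms), names={}, parents=parents, alt_ids={}, root=root
        )
        for t in terms:
            lv = level_of[t]
            if lv < 2 or rng.random() >= extra_edge_prob:
                continue
            shallow = [
                c
                for target_lv in range(1, lv)
                for c in by_level[target_lv]
                if c not in ancestors_of(graph_tmp, t)
            ]
            if shallow:
                new_parent = shallow[int(rng.integers(len(shallow)))]
                parents[t].add(new_parent)
                graph_tmp._ancestor_cache.clear()

    names = {t: f"synthetic term {t}" for t in terms}
    return OntologyGraph(
        terms=set(terms), names=names, parents=parents, alt_ids={}, root=root
    )


def _subtree_leaves(graph: OntologyGraph, size_needed: int) -> tuple[str, list[str]]:
    """Pick the first subtree (by root term order) with >= size_needed leaves,
    preferring deep (specific) subtree roots."""
    leaves = graph.leaves()
    candidates = []
    for term in sorted(graph.terms):
        if term == graph.root:
            continue
        sub = [l for l in leaves if term in ancestors_of(graph, l)]
        if len(sub) >= size_needed:
            candidates.append((term, sub))
    if not candidates:
        raise ValueError("no subtree large enough for the requested term count")
    # deepest qualifying subtree = fewest leaves = most specific planted signal
    candidates.sort(key=lambda c: (len(c[1]), c[0]))
    return candidates[0]


def make_synthetic_corpus(
    graph: OntologyGraph, config: PlantedBenchmarkConfig
) -> tuple[AnnotationCorpus, list[str], str]:
    """Corpus with a planted phenotype-consensus module.

    Returns ``(corpus, module_genes, planted_subtree_root)``.  Every gene
    causes at least one disease; module genes' diseases draw a fraction
    ``effect`` of their terms from the planted subtree and the rest uniformly
    from all leaves; background diseases draw all terms uniformly.
    """
    rng = np.random.default_rng(config.seed)
    leaves = graph.leaves()
    lo, hi = config.terms_per_disease
    if hi > len(leaves):
        raise ValueError("terms_per_disease exceeds the number of ontology leaves")
    subtree_root, subtree_leaves = _subtree_leaves(graph, hi)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    module = genes[: config.module_size]
    n_diseases = max(config.n_diseases, config.n_genes)
    diseases = [f"SYND:{i:05d}" for i in range(n_diseases)]

    disease_terms: dict[str, frozenset[str]] = {}
    gene_diseases: dict[str, frozenset[str]] = {}
    for i, gene in enumerate(genes):
        disease = diseases[i]
        k = int(rng.integers(lo, hi + 1))
        in_module = gene in module
        n_planted = int(round(config.effect * k)) if in_module else 0
        planted = rng.choice(subtree_leaves, size=min(n_planted, len(subtree_leaves)),
                             replace=False).tolist()
        n_rest = k - len(planted)
        rest_pool = [l for l in leaves if l not in planted]
        rest = rng.choice(rest_pool, size=n_rest, replace=False).tolist()
        disease_terms[disease] = frozenset(planted + rest)
        gene_diseases[gene] = frozenset({disease})

    corpus = build_corpus(disease_terms, gene_diseases)
    return corpus, module, subtree_root


def make_synthetic_network(
    genes: Sequence[str],
    module: Sequence[str],
    p_within: float,
    p_between: float,
    seed: int = 0,
) -> Network:
    """Directed two-block random network with scores uniform on (0.5, 1.0).

    Ordered gene pairs inside the module connect with probability
    ``p_within``, all other ordered pairs with ``p_between``.  All scores pass
    the default high-confidence threshold, so threshold behaviour must be
    probed with crafted edges.
    """
    module_set = set(module)
    if not module_set <= set(genes):
        raise ValueError("module must be a subset of genes")
    rng = np.random.default_rng(seed)
    edges: dict[tuple[str, str], float] = {}
    for s in genes:
        for t in genes:
            if s == t:
                continue
            p = p_within if (s in module_set and t in module_set) else p_between
            if rng.random() < p:
                edges[(s, t)] = float(0.5 + 0.5 * rng.random())
    return Network(edges=edges)


def planted_benchmark(
    config: PlantedBenchmarkConfig,
) -> tuple[AnnotationCorpus, OntologyGraph, Network, list[tuple[str, str]]]:
    """Bundle ontology, corpus, network and the module's association list.

    The association list pairs each module gene with one of its diseases,
    ready for leave-one-out evaluation.
    """
    graph = make_toy_ontology(config.depth, config.branching, seed=config.seed)
    corpus, module, _ = make_synthetic_corpus(graph, config)
    network = make_synthetic_network(
        sorted(corpus.gene_diseases), module, config.p_within, config.p_between,
        seed=config.seed + 1,
    )
    associations = [
        (gene, sorted(corpus.gene_diseases[gene])[0]) for gene in module
    ]
    return corpus, graph, network, associations


# ---------------------------------------------------------------------------
# serialization to standard flat formats


def write_obo(graph: OntologyGraph, path) -> None:
    lines = ["format-version: 1.2", "ontology: synthetic-phenotype", ""]
    for term in sorted(graph.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {graph.names.get(term, term)}")
        for alt, canon in sorted(graph.alt_ids.items()):
            if canon == term:
                lines.append(f"alt_id: {alt}")
        for parent in sorted(graph.parents[term]):
            lines.append(f"is_a: {parent}")
        lines.append("")
    _write(path, "\n".join(lines))


def write_disease_annotations(corpus: AnnotationCorpus, path) -> None:
    lines = ["database_id\tdisease_id\thp_id"]
    for disease in sorted(corpus.disease_terms):
        for term in sorted(corpus.disease_terms[disease]):
            lines.append(f"SYNDB\t{disease}\t{term}")
    _write(path, "\n".join(lines) + "\n")


def write_gene_disease_links(corpus: AnnotationCorpus, path) -> None:
    lines = ["gene_id\tdisease_id\tclinical_significance\torigin"]
    for gene in sorted(corpus.gene_diseases):
        for disease in sorted(corpus.gene_diseases[gene]):
            lines.append(f"{gene}\t{disease}\tPathogenic\tgermline")
    _write(path, "\n".join(lines) + "\n")


def write_network(network: Network, path) -> None:
    lines = ["source\ttarget\tscore"]
    for (s, t) in sorted(network.edges):
        lines.append(f"{s}\t{t}\t{network.edges[(s, t)]:.6f}")
    _write(path, "\n".join(lines) + "\n")


def write_gmt(pathways: dict[str, tuple[str, Iterable[str]]], path) -> None:
    lines = []
    for ident in sorted(pathways):
        name, genes = pathways[ident]
        lines.append("\t".join([ident, name] + sorted(genes)))
    _write(path, "\n".join(lines) + "\n")


def _write(path, text: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
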