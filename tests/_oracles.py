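"""Independent brute-force oracles used only by tests.

Deliberately naive implementations that share no code with the package:
ancestor closures by explicit breadth-first walks over the raw parent maps,
similarity by full double loops, the rank-sum null by complete enumeration of
group assignments scored with pairwise comparisons, and AUC by pairwise
enumeration.
"""

import math
from itertools import combinations


def ancestor_closure(parents, term):
    seen = set()
    stack = [term]
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        stack.extend(parents[t])
    return seen


def brute_ic(parents, gene_terms):
    """IC per term from propagated gene counts, -ln(count/omega)."""
    genes = [g for g, ts in gene_terms.items() if ts]
    omega = len(genes)
    counts = {}
    for g in genes:
        covered = set()
        for t in gene_terms[g]:
            covered |= ancestor_closure(parents, t)
        for t in covered:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / omega) for t, c in counts.items()}, counts, omega


def brute_term_sim(parents, ic, t1, t2):
    common = ancestor_closure(parents, t1) & ancestor_closure(parents, t2)
    best = 0.0
    for a in common:
        if a in ic and ic[a] > best:
            best = ic[a]
    return best


def brute_symmetric_sim(parents, ic, q, d):
    q, d = set(q), set(d)
    fwd = sum(max(brute_term_sim(parents, ic, t1, t2) for t2 in d) for t1 in q) / len(q)
    bwd = sum(max(brute_term_sim(parents, ic, t2, t1) for t1 in q) for t2 in d) / len(d)
    return (fwd + bwd) / 2.0


def brute_mwu_greater_p(x, y):
    """Exact one-sided p via the pairwise-comparison U statistic, enumerating
    every assignment of pooled values to the first group."""
    def u_stat(a, b):
        return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in a for yi in b)

    pooled = list(x) + list(y)
    k = len(x)
    observed = u_stat(x, y)
    hits = total = 0
    for idx in combinations(range(len(pooled)), k):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(chosen, rest) >= observed - 1e-9:
            hits += 1
    return hits / total


def brute_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def random_fixture(rng, max_terms=50, max_genes=20):
    """Random DAG ontology + gene annotations for oracle cross-checks.

    Returns (parents, gene_terms): each non-root term gets 1-2 parents among
    earlier terms (guaranteeing acyclicity), each gene 1-4 annotated terms.
    """
    n_terms = int(rng.integers(5, max_terms + 1))
    terms = [f"T{i}" for i in range(n_terms)]
    parents = {terms[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, 3))
        choices = rng.choice(i, size=min(k, i), replace=False)
        parents[terms[i]] = {terms[j] for j in choices}
    n_genes = int(rng.integers(2, max_genes + 1))
    gene_terms = {}
    for g in range(n_genes):
        k = int(rng.integers(1, 5))
        idx = rng.choice(n_terms, size=k, replace=False)
        gene_terms[f"G{g}"] = frozenset(terms[j] for j in idx)
    return parents, gene_terms
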