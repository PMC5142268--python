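"""Ontology handling: OBO parsing, identifier resolution, branch restriction
and ancestor queries.

The ontology is modelled as a DAG over phenotype terms where an ``is_a`` edge
points from a child term to each of its parents.  Only ``is_a`` relationships
define ancestry; ``part_of`` and other relationship types are ignored, since
phenotype-ontology subsumption (and hence the most-informative-common-ancestor
similarity built on top of it) is defined over ``is_a`` alone.

Ancestor sets are *reflexive*: a term is its own ancestor.  This makes the
most informative common ancestor of a term with itself the term itself, with
no special casing downstream.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

from .errors import OboParseError, OntologyCycleError, UnknownTermError

__all__ = [
    "OntologyGraph",
    "parse_obo",
    "resolve_term",
    "restrict_to_branch",
    "ancestors_of",
]


@dataclass
class OntologyGraph:
    """A parsed, possibly branch-restricted ontology.

    Attributes
    ----------
    terms:
        Canonical identifiers of all retained (non-obsolete) terms.
    names:
        Term identifier -> human-readable label.
    parents:
        Term identifier -> set of direct ``is_a`` parents.  Every parent is
        itself a member of ``terms``.
    alt_ids:
        Alternate identifier -> canonical identifier.
    root:
        Root of the restricted branch, or ``None`` for an unrestricted graph.
    """

    terms: set[str]
    names: dict[str, str]
    parents: dict[str, set[str]]
    alt_ids: dict[str, str]
    root: str | None = None
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def children(self) -> dict[str, set[str]]:
        """Inverse of ``parents`` (computed on demand)."""
        out: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                out[p].add(child)
        return out

    def leaves(self) -> list[str]:
        """Terms with no children, in sorted order."""
        ch = self.children()
        return sorted(t for t, c in ch.items() if not c)


_ID_RE = re.compile(r"^id:\s*(\S+)")


def _check_term_stanzas_have_ids(text: str) -> None:
    """Raise OboParseError naming the ordinal of a [Term] stanza lacking id."""
    ordinal = 0
    in_term = False
    has_id = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            if in_term and not has_id:
                raise OboParseError(f"[Term] stanza #{ordinal} has no id field")
            in_term = line == "[Term]"
            if in_term:
                ordinal += 1
                has_id = False
        elif in_term and _ID_RE.match(line):
            has_id = True
    if in_term and not has_id:
        raise OboParseError(f"[Term] stanza #{ordinal} has no id field")


def parse_obo(source: str | IO[str] | IO[bytes]) -> OntologyGraph:
    """Parse an OBO flat file into an :class:`OntologyGraph`.

    Parameters
    ----------
    source:
        Path to an OBO file, or an open text/byte stream of OBO content.

    Non-obsolete ``[Term]`` stanzas become graph terms; ``is_a`` targets are
    recorded as parents, ``alt_id`` entries populate the alternate-identifier
    map, and every other relationship type is ignored.  Obsolete terms are
    dropped entirely (their alternate ids are not chased).

    Raises
    ------
    OboParseError
        If a ``[Term]`` stanza carries no ``id`` field.
    OntologyCycleError
        If the ``is_a`` relation is cyclic.
    """
    if hasattr(source, "read"):
        raw = source.read()
        text = raw.decode() if isinstance(raw, bytes) else raw
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()

    _check_term_stanzas_have_ids(text)
    multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)

    terms: set[str] = set(multigraph.nodes)
    names: dict[str, str] = {}
    parents: dict[str, set[str]] = {t: set() for t in terms}
    alt_ids: dict[str, str] = {}
    for term, data in multigraph.nodes(data=True):
        if "name" in data:
            names[term] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    for child, parent, key in multigraph.edges(keys=True):
        # drop dangling references (e.g. is_a pointing at an obsolete term)
        if key == "is_a" and parent in terms:
            parents[child].add(parent)

    dag = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = [u for u, _ in nx.find_cycle(dag)]
        raise OntologyCycleError(cycle + [cycle[0]])

    return OntologyGraph(terms=terms, names=names, parents=parents, alt_ids=alt_ids)


def resolve_term(graph: OntologyGraph, identifier: str) -> str:
    """Map an identifier to its canonical term.

    Returns ``identifier`` unchanged when it is a canonical term, the canonical
    target when it is a known alternate identifier, and raises
    :class:`UnknownTermError` otherwise (the caller decides drop-vs-fail).
    """
    if identifier in graph.terms:
        return identifier
    if identifier in graph.alt_ids:
        return graph.alt_ids[identifier]
    raise UnknownTermError(identifier)


def ancestors_of(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Reflexive transitive ``is_a`` closure of *term*.

    Memoized per graph; the contract is purely functional.
    """
    if term not in graph.terms:
        raise UnknownTermError(term)
    cache = graph._ancestor_cache
    hit = cache.get(term)
    if hit is not None:
        return hit
    closure: set[str] = {term}
    for parent in graph.parents[term]:
        closure |= ancestors_of(graph, parent)
    result = frozenset(closure)
    cache[term] = result
    return result


def restrict_to_branch(graph: OntologyGraph, root: str) -> OntologyGraph:
    """Restrict the ontology to *root* and its ``is_a`` descendants.

    The returned graph contains exactly the terms with an ``is_a`` path to
    *root* (plus *root* itself); parent sets are pruned to retained terms and
    alternate ids pointing outside the branch are dropped.  Restriction is
    idempotent.
    """
    root = resolve_term(graph, root)
    kept = {t for t in graph.terms if root in ancestors_of(graph, t)}
    parents = {t: graph.parents[t] & kept for t in kept}
    names = {t: graph.names[t] for t in kept if t in graph.names}
    alt_ids = {a: t for a, t in graph.alt_ids.items() if t in kept}
    return OntologyGraph(
        terms=kept, names=names, parents=parents, alt_ids=alt_ids, root=root
    )


def resolve_terms(
    graph: OntologyGraph, identifiers: Iterable[str], *, skip_unresolved: bool = False
) -> tuple[set[str], list[str]]:
    """Resolve many identifiers at once.

    Returns ``(resolved_in_graph, dropped)``.  With ``skip_unresolved`` the
    unresolvable identifiers are collected in ``dropped`` instead of raising.
    """
    resolved: set[str] = set()
    dropped: list[str] = []
    for ident in identifiers:
        try:
            resolved.add(resolve_term(graph, ident))
        except UnknownTermError:
            if not skip_unresolved:
                raise
            dropped.append(ident)
    return resolved, dropped
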