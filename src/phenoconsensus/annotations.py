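"""Gene / disease / phenotype annotation corpus.

A corpus links each Mendelian disease to its phenotype terms (restricted to
the abnormality branch of the ontology) and each gene to the diseases it
causes.  A gene's phenotype profile is the union of the term sets of all its
diseases, and the *universe* is the set of genes carrying at least one term —
the denominator |Omega| of the information-content computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Mapping

import pandas as pd

from .errors import EmptyCorpusError, SchemaError
from .ontology import OntologyGraph, resolve_term
from .errors import UnknownTermError

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationCorpus",
    "DEFAULT_SIGNIFICANCE",
    "DEFAULT_ORIGINS",
    "parse_disease_annotations",
    "parse_gene_disease_links",
    "build_corpus",
    "remove_gene_annotations",
]

#: Clinical-significance labels retained by default.
DEFAULT_SIGNIFICANCE: frozenset[str] = frozenset({"Pathogenic"})

#: Variant-origin labels retained by default (germline transmission modes;
#: somatic and unknown origins are excluded).
DEFAULT_ORIGINS: frozenset[str] = frozenset(
    {
        "germline",
        "de novo",
        "inherited",
        "maternal",
        "paternal",
        "biparental",
        "uniparental",
    }
)


@dataclass(frozen=True)
class AnnotationCorpus:
    """Immutable annotation corpus.

    Attributes
    ----------
    disease_terms:
        Disease identifier -> set of canonical branch terms.
    gene_diseases:
        Gene identifier -> set of disease identifiers it causes.
    gene_terms:
        Gene identifier -> union of ``disease_terms`` over its diseases.
    universe:
        Genes with at least one phenotype term (|Omega| = ``len(universe)``).
    """

    disease_terms: dict[str, frozenset[str]]
    gene_diseases: dict[str, frozenset[str]]
    gene_terms: dict[str, frozenset[str]] = field(init=False)
    universe: frozenset[str] = field(init=False)

    def __post_init__(self):
        gene_terms = {}
        for gene, diseases in self.gene_diseases.items():
            terms = frozenset().union(
                *(self.disease_terms[d] for d in diseases if d in self.disease_terms)
            ) if diseases else frozenset()
            if terms:
                gene_terms[gene] = terms
        object.__setattr__(self, "gene_terms", gene_terms)
        object.__setattr__(self, "universe", frozenset(gene_terms))

    @property
    def omega(self) -> int:
        return len(self.universe)

    def genes_of_disease(self, disease: str) -> frozenset[str]:
        """Genes causally linked to *disease*."""
        return frozenset(
            g for g, ds in self.gene_diseases.items() if disease in ds
        )


def parse_disease_annotations(
    source, graph: OntologyGraph
) -> dict[str, frozenset[str]]:
    """Parse a disease-annotation table into ``disease -> branch term set``.

    The table is TSV with at least three columns: database identifier, disease
    identifier and phenotype term identifier (header optional; lines starting
    with ``#`` are ignored).  Term identifiers are resolved through alternate
    ids; unresolvable terms and terms outside the restricted branch are
    discarded (counts logged).  Diseases whose surviving term set is empty are
    omitted entirely.
    """
    df = _read_tsv(source, ["database_id", "disease_id", "hp_id"])
    out: dict[str, set[str]] = {}
    n_unresolved = 0
    n_out_of_branch = 0
    for disease, hp in zip(df["disease_id"], df["hp_id"]):
        try:
            term = resolve_term(graph, str(hp))
        except UnknownTermError:
            n_unresolved += 1
            continue
        if term not in graph.terms:  # defensive; resolve_term guarantees this
            n_out_of_branch += 1
            continue
        out.setdefault(str(disease), set()).add(term)
    if n_unresolved:
        logger.warning(
            "dropped %d annotation rows with unresolvable or out-of-branch terms",
            n_unresolved,
        )
    if not out:
        logger.warning("disease annotation input produced an empty mapping")
    return {d: frozenset(ts) for d, ts in out.items() if ts}


def parse_gene_disease_links(
    source,
    allowed_significance: frozenset[str] | set[str] = DEFAULT_SIGNIFICANCE,
    allowed_origins: frozenset[str] | set[str] = DEFAULT_ORIGINS,
) -> dict[str, frozenset[str]]:
    """Parse a gene-disease link table into ``gene -> disease set``.

    Rows carry (gene, disease, clinical significance, origin).  A pair is
    retained iff its significance is allowed and at least one of its
    (``;``/``,``-separated) origin labels is allowed; duplicates collapse.
    """
    df = _read_tsv(source, ["gene_id", "disease_id", "clinical_significance", "origin"])
    allowed_significance = {s.lower() for s in allowed_significance}
    allowed_origins = {o.lower() for o in allowed_origins}
    out: dict[str, set[str]] = {}
    for gene, disease, sig, origin in zip(
        df["gene_id"], df["disease_id"], df["clinical_significance"], df["origin"]
    ):
        if str(sig).strip().lower() not in allowed_significance:
            continue
        origins = {o.strip().lower() for o in str(origin).replace(",", ";").split(";")}
        if not origins & allowed_origins:
            continue
        out.setdefault(str(gene), set()).add(str(disease))
    return {g: frozenset(ds) for g, ds in out.items()}


def build_corpus(
    disease_terms: Mapping[str, frozenset[str]],
    gene_diseases: Mapping[str, frozenset[str]],
) -> AnnotationCorpus:
    """Assemble an :class:`AnnotationCorpus` from the two parsed mappings.

    Diseases without branch terms are dropped before linking; genes linked
    only to dropped diseases are excluded from the universe.
    """
    disease_terms = {d: frozenset(ts) for d, ts in disease_terms.items() if ts}
    linked = {
        g: frozenset(d for d in ds if d in disease_terms)
        for g, ds in gene_diseases.items()
    }
    linked = {g: ds for g, ds in linked.items() if ds}
    if not linked:
        raise EmptyCorpusError(
            "no gene is linked to a disease carrying branch phenotype terms"
        )
    return AnnotationCorpus(disease_terms=disease_terms, gene_diseases=linked)


def remove_gene_annotations(corpus: AnnotationCorpus, gene: str) -> AnnotationCorpus:
    """Return a copy of *corpus* with *gene* removed (leave-one-out masking).

    Disease annotations are untouched; only the gene's link into the corpus is
    severed, so it disappears from the universe.  Removing an absent gene is a
    no-op returning an equivalent corpus.
    """
    gene_diseases = {g: ds for g, ds in corpus.gene_diseases.items() if g != gene}
    return AnnotationCorpus(
        disease_terms=corpus.disease_terms, gene_diseases=gene_diseases
    )


def _read_tsv(source, required: list[str]) -> pd.DataFrame:
    """Read a headered or headerless TSV with the given logical columns."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str, header=None)
    if df.empty:
        return pd.DataFrame(columns=required)
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if set(required) <= set(first):
        df.columns = first
        df = df.iloc[1:].reset_index(drop=True)
        return df[required]
    if df.shape[1] < len(required):
        missing = required[df.shape[1]:]
        raise SchemaError(f"input is missing required column(s): {missing}")
    df = df.iloc[:, : len(required)]
    df.columns = required
    return df
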