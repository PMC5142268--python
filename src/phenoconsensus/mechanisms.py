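"""Mechanism sampling: related genes from networks, pathways or custom lists.

A candidate gene's "mechanism" is sampled either as its neighbors in a
directed, scored interaction network (optionally restricted to upstream or
downstream partners and to high-confidence edges) or as the co-members of the
pathways it belongs to.  Custom gene lists may be used anywhere a pathway
member set is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable

import pandas as pd

from .errors import TableParseError

__all__ = [
    "Network",
    "PathwayCollection",
    "parse_network",
    "neighbor_genes",
    "parse_pathways",
    "candidate_pathways",
]

DIRECTIONS = ("all", "upstream", "downstream")


@dataclass(frozen=True)
class Network:
    """Directed scored interaction network.

    ``edges`` maps (source, target) -> score in [0, 1]; self-loops are never
    retained and duplicate directed edges collapse keeping the maximum score.
    """

    edges: dict[tuple[str, str], float]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s, t in self.edges:
            out.add(s)
            out.add(t)
        return frozenset(out)


@dataclass(frozen=True)
class PathwayCollection:
    """Pathway identifier -> (name, member gene set)."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.pathways)


def parse_network(
    source,
    *,
    normalize: bool | None = None,
    undirected: bool = False,
) -> Network:
    """Parse a TSV edge list (source, target, score) into a :class:`Network`.

    Scores on a 0-1000 integer scale are auto-detected (any score > 1) and
    divided by 1000 so thresholds are always interpreted on [0, 1]; pass
    ``normalize=True``/``False`` to force or forbid the rescaling.  With
    ``undirected=True`` every edge is mirrored.
    """
    df = _read_edge_tsv(source)
    scores = df["score"].tolist()
    if normalize is None:
        normalize = bool(scores) and max(scores) > 1.0
    edges: dict[tuple[str, str], float] = {}
    for s, t, w in zip(df["source"], df["target"], scores):
        if s == t:
            continue
        w = w / 1000.0 if normalize else w
        pairs = [(s, t), (t, s)] if undirected else [(s, t)]
        for key in pairs:
            if w > edges.get(key, -1.0):
                edges[key] = w
    return Network(edges=edges)


def neighbor_genes(
    network: Network,
    gene: str,
    direction: str = "all",
    min_score: float = 0.5,
) -> frozenset[str]:
    """Interaction neighbors of *gene* passing the confidence threshold.

    ``upstream`` neighbors are sources of edges into the gene, ``downstream``
    neighbors are targets of edges out of it, ``all`` is their union.  The
    gene itself is always excluded; an absent gene yields the empty set.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    out: set[str] = set()
    for (s, t), w in network.edges.items():
        if w < min_score:
            continue
        if direction in ("all", "downstream") and s == gene:
            out.add(t)
        if direction in ("all", "upstream") and t == gene:
            out.add(s)
    out.discard(gene)
    return frozenset(out)


def parse_pathways(source) -> PathwayCollection:
    """Parse a GMT stream (identifier, description, genes...) into pathways."""
    if hasattr(source, "read"):
        lines = source.read()
        if isinstance(lines, bytes):
            lines = lines.decode()
        lines = lines.splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise TableParseError(
                f"GMT row {i} has {len(fields)} field(s); need identifier, "
                "description and at least one gene"
            )
        ident, name, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise TableParseError(f"GMT row {i} lists no genes")
        pathways[ident] = (name, frozenset(genes))
    return PathwayCollection(pathways=pathways)


def candidate_pathways(
    collection: PathwayCollection, gene: str
) -> list[tuple[str, frozenset[str]]]:
    """Pathways containing *gene*, each without the candidate itself.

    Returned sorted by pathway identifier for determinism; a pathway whose
    only member is the candidate yields an empty member set.
    """
    out = []
    for ident in sorted(collection.pathways):
        name, members = collection.pathways[ident]
        if gene in members:
            out.append((ident, members - {gene}))
    return out


def _read_edge_tsv(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str, header=None)
    if df.empty:
        return pd.DataFrame(columns=["source", "target", "score"])
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if {"source", "target", "score"} <= set(first):
        df.columns = first
        df = df.iloc[1:].reset_index(drop=True)
    else:
        if df.shape[1] < 3:
            raise TableParseError("edge list needs source, target and score columns")
        df = df.iloc[:, :3]
        df.columns = ["source", "target", "score"]
    df = df[["source", "target", "score"]].copy()
    try:
        df["score"] = df["score"].astype(float)
    except ValueError:
        bad = df.index[pd.to_numeric(df["score"], errors="coerce").isna()][0]
        raise TableParseError(f"non-numeric score in edge-list row {bad + 1}")
    return df
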