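"""Edge-list, GMT and table I/O.

Networks are plain :class:`networkx.Graph` objects: simple, undirected,
string-labelled nodes, with the original interaction confidence kept as the
``score`` edge attribute for provenance only (all topology metrics run on the
unweighted graph).

The edge-list dialect is the STRING-export style TSV:
``node1<TAB>node2[<TAB>combined_score]``.  STRING distributes combined scores
both as fractions in [0, 1] and as integers in [0, 1000]; if any score in the
column exceeds 1 the whole column is taken to be the integer dialect and is
divided by 1000 before thresholding.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import networkx as nx

from .errors import EdgeListParseError

_HEADER_TOKENS = {
    "node1", "node2", "protein1", "protein2", "source", "target",
    "item_id_a", "item_id_b", "gene1", "gene2", "score", "combined_score",
    "weight", "confidence",
}


def _looks_like_header(fields: list[str]) -> bool:
    if len(fields) >= 3:
        try:
            float(fields[2])
            return False
        except ValueError:
            return True
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields[:2])


def load_scored_edges(path: str | os.PathLike, score_min: float = 0.4) -> nx.Graph:
    """Load a scored TSV edge list, keeping edges with score >= ``score_min``.

    Self-loops are dropped (the node is retained); duplicate pairs are merged
    keeping the maximum score; a score column in the STRING integer dialect
    (any value > 1) is rescaled by 1/1000 before thresholding.  Rows without a
    score column always pass the threshold.

    Raises
    ------
    ValueError
        If ``score_min`` is outside [0, 1].
    EdgeListParseError
        On a malformed line, naming its line number.
    """
    if not 0.0 <= score_min <= 1.0:
        raise ValueError(f"score_min must lie in [0, 1], got {score_min}")

    rows: list[tuple[str, str, float | None]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate whitespace-separated exports
                fields = line.split()
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 2:
                raise EdgeListParseError(lineno, f"expected >= 2 columns, got {len(fields)}")
            u, v = fields[0].strip(), fields[1].strip()
            if not u or not v:
                raise EdgeListParseError(lineno, "empty node identifier")
            score: float | None = None
            if len(fields) >= 3 and fields[2].strip():
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise EdgeListParseError(lineno, f"unparseable score {fields[2]!r}") from exc
            rows.append((u, v, score))

    scores = [s for _, _, s in rows if s is not None]
    rescale = 1e-3 if any(s > 1.0 for s in scores) else 1.0

    G = nx.Graph()
    for u, v, score in rows:
        G.add_node(u)
        G.add_node(v)
        if u == v:
            continue
        s = None if score is None else score * rescale
        if G.has_edge(u, v):
            prev = G.edges[u, v].get("score")
            if s is not None and (prev is None or s > prev):
                G.edges[u, v]["score"] = s
        else:
            if s is None:
                G.add_edge(u, v)
            else:
                G.add_edge(u, v, score=s)

    drop = [
        (u, v)
        for u, v, d in G.edges(data=True)
        if d.get("score") is not None and d["score"] < score_min
    ]
    G.remove_edges_from(drop)
    return G


def write_edges(G: nx.Graph, path: str | os.PathLike) -> None:
    """Write a TSV edge list (scores included where present) that
    :func:`load_scored_edges` round-trips exactly."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("node1\tnode2\tscore\n")
        for u, v, d in sorted(G.edges(data=True)):
            s = d.get("score")
            fh.write(f"{u}\t{v}\t{'' if s is None else repr(s)}\n")
        for n in sorted(G.nodes):
            if G.degree(n) == 0:
                fh.write(f"{n}\t{n}\t\n")  # self-loop row: node retained, edge dropped


def write_graphml(G: nx.Graph, path: str | os.PathLike) -> None:
    nx.write_graphml(G, path)


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT annotation collection: ``term<TAB>description<TAB>member...``."""
    collection: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EdgeListParseError(lineno, "GMT line needs term, description, >= 1 member")
            collection[fields[0]] = {m for m in fields[2:] if m}
    return collection


def write_gmt(collection: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for term in sorted(collection):
            members = "\t".join(sorted(collection[term]))
            fh.write(f"{term}\tna\t{members}\n")


def load_node_set(path: str | os.PathLike) -> set[str]:
    """One node identifier per line; blank lines and ``#`` comments skipped."""
    out: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            tok = raw.strip()
            if tok and not tok.startswith("#"):
                out.add(tok)
    return out
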