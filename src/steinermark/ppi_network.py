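"""Load PPI edge lists, extract the largest connected component, map terminals.

The network container is a :class:`networkx.Graph` with a positive ``weight``
attribute on every edge. Gene identifiers are opaque strings; any cross-platform
identifier mapping is the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Union

import networkx as nx

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class EdgeListParseError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from one :func:`load_edge_list` call."""

    n_data_lines: int
    n_edges: int
    self_loops: int
    duplicates: int


@dataclass(frozen=True)
class TerminalSet:
    """Genes from a query list that map onto the network (the required vertices).

    ``terminals`` are present in the network; ``dropped`` records requested
    identifiers absent from it (e.g. genes measured on a platform but missing
    from the interaction data).
    """

    terminals: frozenset
    dropped: frozenset = frozenset()

    def __post_init__(self):
        if self.terminals & self.dropped:
            raise ValueError("terminals and dropped sets must be disjoint")

    def __len__(self) -> int:
        return len(self.terminals)

    def __iter__(self):
        return iter(self.terminals)


def _open(source: Union[PathLike, IO[str]]):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def load_edge_list(
    source: Union[PathLike, IO[str]],
    *,
    sif: bool = False,
    default_weight: float = 1.0,
) -> nx.Graph:
    """Read an undirected edge list into a weighted :class:`networkx.Graph`.

    Each data line holds two whitespace-separated gene identifiers, optionally
    followed by a numeric weight; lines starting with ``#`` are comments. With
    ``sif=True`` the second token (the interaction type) is ignored and every
    following token is a target node, as in the SIF dialect.

    Self-loops are discarded (public PPI dumps contain them) and duplicate
    edges — including reversed duplicates — are collapsed, keeping the first
    weight seen. Counts land in ``graph.graph["load_report"]``.

    Raises
    ------
    EdgeListParseError
        On a line with a single token, a non-numeric weight, a non-positive
        weight, or when the input contains no edges at all.
    """
    fh, should_close = _open(source)
    g = nx.Graph()
    n_lines = self_loops = duplicates = 0
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            tokens = line.split()
            if sif:
                if len(tokens) < 3:
                    raise EdgeListParseError(
                        f"line {lineno}: SIF line needs 'source type target...', got {len(tokens)} tokens"
                    )
                pairs = [(tokens[0], t, default_weight) for t in tokens[2:]]
            else:
                if len(tokens) < 2:
                    raise EdgeListParseError(f"line {lineno}: expected at least 2 tokens, got {len(tokens)}")
                if len(tokens) >= 3:
                    try:
                        w = float(tokens[2])
                    except ValueError as exc:
                        raise EdgeListParseError(f"line {lineno}: weight {tokens[2]!r} is not numeric") from exc
                else:
                    w = default_weight
                if not w > 0:
                    raise EdgeListParseError(f"line {lineno}: edge weight must be positive, got {w}")
                pairs = [(tokens[0], tokens[1], w)]
            for u, v, w in pairs:
                if u == v:
                    self_loops += 1
                    continue
                if g.has_edge(u, v):
                    duplicates += 1
                    continue
                g.add_edge(u, v, weight=float(w))
    finally:
        if should_close:
            fh.close()
    if n_lines == 0:
        raise EdgeListParseError("empty input: no data lines")
    if g.number_of_edges() == 0:
        raise EdgeListParseError("input contains no usable edges (all self-loops?)")
    g.graph["load_report"] = LoadReport(
        n_data_lines=n_lines,
        n_edges=g.number_of_edges(),
        self_loops=self_loops,
        duplicates=duplicates,
    )
    return g


def write_edge_list(net: nx.Graph, target: Union[PathLike, IO[str]]) -> None:
    """Write the network as a three-column (u, v, weight) tab-separated file.

    Edges are emitted in lexicographic order so output is byte-deterministic.
    """
    if hasattr(target, "write"):
        fh, should_close = target, False
    else:
        fh, should_close = open(target, "w", encoding="utf-8"), True
    try:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            w = net[u][v].get("weight", 1.0)
            fh.write(f"{u}\t{v}\t{w:.17g}\n")
    finally:
        if should_close:
            fh.close()


def load_gene_list(source: Union[PathLike, IO[str]]) -> list:
    """Read one gene identifier per line ('#' comments allowed); order-preserving, deduplicated."""
    fh, should_close = _open(source)
    seen = set()
    genes = []
    try:
        for raw in fh:
            tok = raw.strip()
            if not tok or tok.startswith("#"):
                continue
            name = tok.split()[0]
            if name not in seen:
                seen.add(name)
                genes.append(name)
    finally:
        if should_close:
            fh.close()
    return genes


def set_unit_weights(net: nx.Graph) -> nx.Graph:
    """Return a copy with every edge weight reset to 1.0 (the unweighted framing)."""
    out = net.copy()
    nx.set_edge_attributes(out, 1.0, "weight")
    return out


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Node-induced subgraph on the largest connected component.

    Size ties are broken by the lexicographically smallest member identifier,
    so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    components = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    sub = net.subgraph(components[0]).copy()
    sub.graph.update(net.graph)
    return sub


def restrict_terminals(net: nx.Graph, genes: Iterable[str]) -> TerminalSet:
    """Intersect a gene list with the network's nodes, recording what was dropped."""
    requested = frozenset(genes)
    if not requested:
        raise ValueError("gene list is empty")
    present = requested & frozenset(net.nodes())
    dropped = requested - present
    if not present:
        raise ValueError("no terminal maps to network")
    if dropped:
        logger.warning("%d of %d query genes are absent from the network", len(dropped), len(requested))
    return TerminalSet(terminals=present, dropped=dropped)
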