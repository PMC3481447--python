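"""Shortest-path-heuristic Steiner trees, plus an exact brute-force oracle.

The heuristic is the classic polynomial-time 2-approximation: grow a forest
over the terminal vertices by repeatedly joining the two closest components
along a weighted shortest path, then refine with a minimum spanning tree of
the induced subgraph and iterative pruning of non-terminal leaves.

Internal (degree > 1) vertices of the resulting tree — Steiner vertices plus
non-leaf terminals — are the candidate markers used downstream.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .ppi_network import TerminalSet


def _edge_key(u, v):
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class SteinerTree:
    """A tree spanning a terminal set within a host network.

    ``vertices`` may include non-terminal (Steiner) vertices recruited to
    connect the terminals; every leaf of a valid tree is a terminal.
    """

    vertices: frozenset
    edges: frozenset  # unordered pairs stored as sorted 2-tuples
    terminals: frozenset
    total_weight: float

    @property
    def steiner_vertices(self) -> frozenset:
        return self.vertices - self.terminals

    def degrees(self) -> dict:
        deg = {v: 0 for v in self.vertices}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    @property
    def leaves(self) -> frozenset:
        return frozenset(v for v, d in self.degrees().items() if d == 1)

    def __len__(self) -> int:
        return len(self.vertices)


def internal_vertices(tree: SteinerTree) -> frozenset:
    """All vertices with tree-degree > 1: Steiner vertices plus non-leaf terminals.

    Because non-terminal leaves are pruned during construction, this is
    exactly the union of Steiner vertices and internal terminals.
    """
    return frozenset(v for v, d in tree.degrees().items() if d > 1)


def _as_terminal_names(terminals) -> list:
    if isinstance(terminals, TerminalSet):
        names = terminals.terminals
    else:
        names = set(terminals)
    if not names:
        raise ValueError("terminal set is empty")
    return sorted(names)


class SteinerSolver:
    """Shortest-path-heuristic solver bound to one network.

    Building the solver converts the graph once to an index/CSR form; each
    :meth:`solve` call may supply a fresh edge-weight vector (aligned with
    :attr:`edge_list`, which is sorted lexicographically), so the randomized
    ensemble can reuse the structure across hundreds of re-weightings.
    """

    def __init__(self, net: nx.Graph):
        if net.number_of_nodes() == 0:
            raise ValueError("network is empty")
        self.nodes: list = sorted(net.nodes())
        self.index = {v: i for i, v in enumerate(self.nodes)}
        n = len(self.nodes)
        keys = sorted(_edge_key(u, v) for u, v in net.edges())
        self.edge_list: list = keys
        self.eu = np.array([self.index[u] for u, _ in keys], dtype=np.int64)
        self.ev = np.array([self.index[v] for _, v in keys], dtype=np.int64)
        self.base_weights = np.array(
            [net[u][v].get("weight", 1.0) for u, v in keys], dtype=float
        )
        if np.any(self.base_weights <= 0):
            raise ValueError("all edge weights must be strictly positive")
        self._rows = np.concatenate([self.eu, self.ev])
        self._cols = np.concatenate([self.ev, self.eu])
        self._n = n

    @property
    def n_edges(self) -> int:
        return len(self.edge_list)

    def _matrix(self, weights: np.ndarray) -> csr_matrix:
        data = np.concatenate([weights, weights])
        return csr_matrix((data, (self._rows, self._cols)), shape=(self._n, self._n))

    def solve(self, terminals, weights: Optional[np.ndarray] = None) -> SteinerTree:
        """Run the four-step heuristic for one terminal set and weight vector."""
        term_names = _as_terminal_names(terminals)
        missing = [t for t in term_names if t not in self.index]
        if missing:
            raise ValueError(f"terminals not present in network: {missing}")
        if weights is None:
            w = self.base_weights
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != self.base_weights.shape:
                raise ValueError("weight vector length does not match edge count")
            if np.any(w <= 0):
                raise ValueError("all edge weights must be strictly positive")

        term_idx = [self.index[t] for t in term_names]
        if len(term_idx) == 1:
            return SteinerTree(
                vertices=frozenset(term_names),
                edges=frozenset(),
                terminals=frozenset(term_names),
                total_weight=0.0,
            )

        A = self._matrix(w)
        _, labels = connected_components(A, directed=False)
        term_labels = labels[term_idx]
        if len(set(term_labels.tolist())) > 1:
            from collections import Counter

            counts = Counter(term_labels.tolist())
            main = max(counts, key=lambda c: (counts[c], -c))
            offenders = [t for t, lab in zip(term_names, term_labels) if lab != main]
            raise ValueError(
                f"terminals lie in different connected components; disconnected from the rest: {offenders}"
            )

        tvertices = self._grow_forest(A, term_idx)
        tree_edges = self._induced_mst(tvertices, w)
        tree_edges, kept = self._prune_leaves(tree_edges, set(term_idx))

        names = self.nodes
        edge_names = frozenset(_edge_key(names[i], names[j]) for i, j, _ in tree_edges)
        total = float(sum(ew for _, _, ew in tree_edges))
        return SteinerTree(
            vertices=frozenset(names[i] for i in kept),
            edges=edge_names,
            terminals=frozenset(term_names),
            total_weight=total,
        )

    # -- step 2: forest merging ------------------------------------------------

    def _grow_forest(self, A: csr_matrix, term_idx: list) -> set:
        """Merge forest components along minimum shortest-path distances.

        Distances in the host graph are fixed for the duration of one solve, so
        single-source rows are computed once per forest vertex (batched) and
        cached; the closest inter-component pair is an argmin over the cached
        pairwise matrix with same-component pairs masked out. Equal distances
        are broken by the lexicographically smallest (u, v) identifier pair.
        """
        n = self._n
        k0 = len(term_idx)
        cap = max(4 * k0 + 16, 32)

        order: list = []  # row position -> node index
        pos: dict = {}  # node index -> row position
        dist_rows: list = []
        pred_rows: list = []
        comp = np.empty(cap, dtype=np.int64)
        D = np.full((cap, cap), np.inf)

        def grow(new_cap):
            nonlocal cap, comp, D
            new_cap = max(new_cap, 2 * cap)
            comp2 = np.empty(new_cap, dtype=np.int64)
            comp2[: len(order)] = comp[: len(order)]
            D2 = np.full((new_cap, new_cap), np.inf)
            D2[: len(order), : len(order)] = D[: len(order), : len(order)]
            cap, comp, D = new_cap, comp2, D2

        def add_vertices(new_idx: list, comp_id: int):
            if not new_idx:
                return
            if len(order) + len(new_idx) > cap:
                grow(len(order) + len(new_idx))
            dist, pred = dijkstra(A, directed=True, indices=new_idx, return_predecessors=True)
            dist = np.atleast_2d(dist)
            pred = np.atleast_2d(pred)
            for r, node in enumerate(new_idx):
                p = len(order)
                order.append(node)
                pos[node] = p
                dist_rows.append(dist[r])
                pred_rows.append(pred[r])
                comp[p] = comp_id
                cols = np.fromiter(order, dtype=np.int64)
                D[p, : p + 1] = dist[r][cols]
                D[: p + 1, p] = D[p, : p + 1]

        # initialize: one singleton component per terminal
        dist, pred = dijkstra(A, directed=True, indices=term_idx, return_predecessors=True)
        for r, node in enumerate(term_idx):
            p = len(order)
            order.append(node)
            pos[node] = p
            dist_rows.append(dist[r])
            pred_rows.append(pred[r])
            comp[p] = r
        cols = np.fromiter(order, dtype=np.int64)
        for p in range(len(order)):
            D[p, : len(order)] = dist_rows[p][cols]

        n_comps = k0
        while n_comps > 1:
            k = len(order)
            Dk = D[:k, :k]
            mask = comp[:k, None] == comp[None, :k]
            Dm = np.where(mask, np.inf, Dk)
            mval = Dm.min()
            if not np.isfinite(mval):
                raise RuntimeError("forest components are mutually unreachable")  # pre excludes this
            ties = np.argwhere(Dm == mval)
            names = self.nodes
            best = None
            for a, b in ties:
                na, nb = names[order[a]], names[order[b]]
                key = (na, nb) if na <= nb else (nb, na)
                if best is None or key < best[0]:
                    best = (key, int(a), int(b))
            _, upos, vpos = best
            u_node, v_node = order[upos], order[vpos]

            # reconstruct the shortest u-v path from u's predecessor row
            pred_u = pred_rows[upos]
            path = [v_node]
            while path[-1] != u_node:
                path.append(int(pred_u[path[-1]]))
            merged = {int(comp[upos]), int(comp[vpos])}
            new_nodes = []
            for x in path:
                if x in pos:
                    merged.add(int(comp[pos[x]]))
                else:
                    new_nodes.append(x)
            target = min(merged)
            sel = np.isin(comp[:k], list(merged))
            comp[:k][sel] = target
            add_vertices(new_nodes, target)
            n_comps -= len(merged) - 1

        return set(order)

    # -- step 3: MST of the induced subgraph ----------------------------------

    def _induced_mst(self, tvertices: set, w: np.ndarray) -> list:
        """Kruskal MST of the subgraph induced by the forest vertices.

        Tie-break on equal weights: lexicographic order of the endpoint pair
        (endpoint indices follow the sorted node list).
        """
        member = np.zeros(self._n, dtype=bool)
        member[list(tvertices)] = True
        cand = np.nonzero(member[self.eu] & member[self.ev])[0]
        cand = sorted(cand, key=lambda e: (w[e], int(self.eu[e]), int(self.ev[e])))
        parent = {v: v for v in tvertices}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        tree = []
        for e in cand:
            i, j = int(self.eu[e]), int(self.ev[e])
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                tree.append((i, j, float(w[e])))
                if len(tree) == len(tvertices) - 1:
                    break
        if len(tree) != len(tvertices) - 1:
            raise RuntimeError("induced subgraph is not connected")  # forest growth guarantees it is
        return tree

    # -- step 4: prune non-terminal leaves ------------------------------------

    @staticmethod
    def _prune_leaves(tree_edges: list, term_idx: set):
        adj: dict = {}
        for i, j, ew in tree_edges:
            adj.setdefault(i, {})[j] = ew
            adj.setdefault(j, {})[i] = ew
        queue = [v for v, nb in adj.items() if len(nb) == 1 and v not in term_idx]
        while queue:
            v = queue.pop()
            if v in term_idx or len(adj.get(v, ())) != 1:
                continue
            (u,) = adj[v]
            del adj[v]
            del adj[u][v]
            if len(adj[u]) == 1 and u not in term_idx:
                queue.append(u)
        kept = set(adj)
        edges = [(i, j, ew) for i, j, ew in tree_edges if i in kept and j in kept and j in adj.get(i, ())]
        if not kept:  # |R| >= 2 always leaves terminals behind; guard for safety
            kept = set(term_idx)
        return edges, kept


def steiner_shortest_path_heuristic(net: nx.Graph, terminals) -> SteinerTree:
    """Approximate Steiner tree over ``terminals`` using the graph's own weights.

    Convenience wrapper constructing a throwaway :class:`SteinerSolver`; use the
    solver directly when running many re-weighted instances of the same graph.
    """
    return SteinerSolver(net).solve(terminals)


def steiner_exact_bruteforce(net: nx.Graph, terminals, max_nodes: int = 16) -> SteinerTree:
    """Exact minimum Steiner tree by exhaustive enumeration (test oracle only).

    Enumerates subsets of non-terminal vertices; for each subset whose union
    with the terminals induces a connected subgraph, the subgraph's MST weight
    is a candidate. The minimum over all subsets is the optimal Steiner tree
    weight. Exponential in the number of non-terminals — refuses graphs larger
    than ``max_nodes``.
    """
    if net.number_of_nodes() > max_nodes:
        raise ValueError(
            f"graph has {net.number_of_nodes()} nodes; brute force is limited to {max_nodes}"
        )
    term_names = _as_terminal_names(terminals)
    missing = [t for t in term_names if t not in net]
    if missing:
        raise ValueError(f"terminals not present in network: {missing}")
    others = sorted(set(net.nodes()) - set(term_names))
    best = None
    best_w = np.inf
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            u_set = set(term_names) | set(extra)
            sub = net.subgraph(u_set)
            if not nx.is_connected(sub):
                continue
            mst = nx.minimum_spanning_tree(sub, weight="weight")
            wsum = mst.size(weight="weight")
            if wsum < best_w - 1e-12:
                best_w = wsum
                best = mst
    if best is None:
        raise ValueError("terminals cannot be connected within the graph")

    tset = set(term_names)
    work = best.copy()
    leaves = [v for v in work if work.degree(v) == 1 and v not in tset]
    while leaves:
        work.remove_nodes_from(leaves)
        leaves = [v for v in work if work.degree(v) == 1 and v not in tset]
    if work.number_of_nodes() == 0:  # |R| == 1 degenerate case
        work.add_nodes_from(term_names)
    return SteinerTree(
        vertices=frozenset(work.nodes()),
        edges=frozenset(_edge_key(u, v) for u, v in work.edges()),
        terminals=frozenset(term_names),
        total_weight=float(work.size(weight="weight")),
    )


def save_tree(tree: SteinerTree, edges_path, meta_path) -> None:
    """Serialize a tree as an edge-list file plus a JSON sidecar."""
    with open(edges_path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tree.edges):
            fh.write(f"{u}\t{v}\n")
    meta = {
        "terminals": sorted(tree.terminals),
        "steiner_vertices": sorted(tree.steiner_vertices),
        "internal_vertices": sorted(internal_vertices(tree)),
        "n_vertices": len(tree.vertices),
        "total_weight": tree.total_weight,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
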