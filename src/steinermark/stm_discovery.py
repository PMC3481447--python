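"""Randomized Steiner-tree ensembles and the union of internal vertices (STMs).

A single Steiner tree is one of many near-optimal solutions; on an unweighted
PPI network the heuristic's tie-breaking hides alternative connector paths.
Drawing every edge weight uniformly from [0.99, 1.0) breaks ties at random,
so repeated runs explore alternative and redundant paths. The union of
internal tree vertices across the ensemble is the Steiner-tree-based marker
(STM) set; the per-iteration trace of newly added genes tracks saturation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .overlap_stats import OverlapResult, overlap_result
from .ppi_network import TerminalSet, largest_connected_component
from .steiner_core import SteinerSolver, _edge_key, internal_vertices

logger = logging.getLogger(__name__)


@dataclass
class PerturbationConfig:
    """Ensemble parameters.

    weight_low, weight_high
        Support of the uniform per-edge weight draw (dimensionless). The narrow
        default band [0.99, 1.0) keeps every path's weight within 1% of its hop
        count, so perturbation acts as random tie-breaking rather than a change
        of objective.
    max_iterations
        Hard cap on ensemble size.
    patience
        Stop after this many consecutive iterations that add no new STM.
    seed
        Master seed; iteration i uses the substream (seed, i), so results do
        not depend on when early stopping triggers.
    """

    weight_low: float = 0.99
    weight_high: float = 1.0
    max_iterations: int = 500
    patience: int = 50
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.weight_low < self.weight_high:
            raise ValueError("require 0 < weight_low < weight_high")
        if self.max_iterations < 1 or self.patience < 1:
            raise ValueError("max_iterations and patience must be positive")
        if self.patience > self.max_iterations:
            raise ValueError("patience must not exceed max_iterations")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass(frozen=True)
class STMSet:
    """Union of internal tree vertices over a randomized ensemble, with trace."""

    genes: frozenset
    n_iterations: int
    per_iteration_new: tuple
    gene_frequency: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if sum(self.per_iteration_new) != len(self.genes):
            raise ValueError("per-iteration trace does not sum to the gene count")

    @property
    def cumulative_counts(self) -> tuple:
        return tuple(np.cumsum(self.per_iteration_new).tolist())

    def __len__(self) -> int:
        return len(self.genes)


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, iteration]))


def perturb_weights(
    net: nx.Graph,
    rng: np.random.Generator,
    weight_low: float = 0.99,
    weight_high: float = 1.0,
) -> nx.Graph:
    """Copy of ``net`` with each edge weight drawn uniformly from the given band.

    Edges are visited in lexicographic order of their endpoint pair, so a given
    generator state always produces the same weight map.
    """
    if not 0 < weight_low < weight_high:
        raise ValueError("require 0 < weight_low < weight_high")
    out = net.copy()
    keys = sorted(_edge_key(u, v) for u, v in net.edges())
    draws = rng.uniform(weight_low, weight_high, size=len(keys))
    for (u, v), w in zip(keys, draws):
        out[u][v]["weight"] = float(w)
    return out


def discover_stms(
    net: nx.Graph,
    terminals,
    config: Optional[PerturbationConfig] = None,
    *,
    progress: bool = False,
) -> STMSet:
    """Run the randomized ensemble and return the union of internal vertices.

    The network is first restricted to its largest connected component and the
    terminals intersected with it (terminals outside are dropped with a
    warning). Each iteration re-draws all edge weights from
    [weight_low, weight_high), solves the shortest-path heuristic, and adds the
    tree's internal vertices to the union. Stops after ``patience`` consecutive
    iterations without a new gene, or at ``max_iterations``.
    """
    if config is None:
        config = PerturbationConfig()
    lcc = largest_connected_component(net)
    names = terminals.terminals if isinstance(terminals, TerminalSet) else frozenset(terminals)
    inside = names & frozenset(lcc.nodes())
    if not inside:
        raise ValueError("no terminal lies in the network's largest connected component")
    if inside != names:
        logger.warning(
            "%d terminals outside the largest connected component were dropped",
            len(names) - len(inside),
        )

    solver = SteinerSolver(lcc)
    genes: set = set()
    freq: Counter = Counter()
    trace = []
    zero_streak = 0
    n_done = 0
    for i in range(config.max_iterations):
        rng = _iteration_rng(config.seed, i)
        w = rng.uniform(config.weight_low, config.weight_high, size=solver.n_edges)
        tree = solver.solve(inside, w)
        internal = internal_vertices(tree)
        fresh = internal - genes
        genes |= internal
        freq.update(internal)
        trace.append(len(fresh))
        n_done = i + 1
        if progress:
            logger.info(
                "iteration %d: tree size %d, %d new STMs (total %d)",
                n_done,
                len(tree),
                len(fresh),
                len(genes),
            )
        zero_streak = zero_streak + 1 if not fresh else 0
        if zero_streak >= config.patience:
            break
    return STMSet(
        genes=frozenset(genes),
        n_iterations=n_done,
        per_iteration_new=tuple(trace),
        gene_frequency=dict(freq),
    )


def stability_report(stms_a: STMSet, stms_b: STMSet, N: int) -> OverlapResult:
    """Cross-set stability: overlap statistics of two STM sets against background N."""
    if N < len(stms_a.genes | stms_b.genes):
        raise ValueError("background N is smaller than the union of the two gene sets")
    o = len(stms_a.genes & stms_b.genes)
    return overlap_result(N, len(stms_a.genes), len(stms_b.genes), o)
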