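"""Synthetic PPI networks, planted connectors, and two-class expression data.

Real inputs to the pipeline are a PPI network, a differential-expression gene
list, and a microarray matrix. This module emulates all three at desk scale so
every stage can be exercised end to end: a preferential-attachment network
stands in for the heavy-tailed PPI degree distribution; a set of hub
"connector" genes is planted so that the differentially expressed (DE) genes
cluster in the connectors' neighborhoods — operationalizing the premise that
disease genes sit on paths between DE genes; and the expression matrix adds a
mean shift on DE genes over Gaussian noise.

The generators are pure functions of their seeds. Defaults (2000 genes, 100
DE genes, 20 connectors, 200 samples, 2 SD effect) are the study conditions
for the recovery and classification checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import ExpressionDataset
from .ppi_network import write_edge_list


@dataclass(frozen=True)
class ScenarioParams:
    n_nodes: int = 2000
    edges_per_node: int = 3
    n_de: int = 100
    n_connectors: int = 20
    n_samples: int = 200
    effect_size: float = 2.0  # class-mean shift on DE genes, in units of noise_sd
    noise_sd: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class SyntheticScenario:
    network: nx.Graph = field(compare=False)
    de_genes: frozenset
    planted_connectors: frozenset
    expression: ExpressionDataset = field(compare=False)
    params: ScenarioParams = field(default_factory=ScenarioParams)


def _child_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def _gene_names(n: int) -> list:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_scale_free_network(n_nodes: int, edges_per_node: int = 3, seed: int = 0) -> nx.Graph:
    """Connected preferential-attachment (Barabási–Albert) network, unit weights."""
    if n_nodes < edges_per_node + 1:
        raise ValueError("need n_nodes >= edges_per_node + 1")
    raw = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=_child_seed(seed, 1))
    names = _gene_names(n_nodes)
    g = nx.relabel_nodes(raw, dict(enumerate(names)))
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def plant_connectors(net: nx.Graph, n_de: int, n_connectors: int, seed: int = 0) -> tuple:
    """Choose hub connectors and DE genes clustered around them.

    Connectors are the highest-degree nodes subject to being pairwise
    non-adjacent (so no connector can be bypassed via a direct edge between
    two connectors). DE genes are drawn from the connectors' neighborhoods
    first — placing the connectors on many shortest paths between DE genes —
    topped up from the remaining nodes if the neighborhoods are too small.
    Returns disjoint ``(de_genes, planted_connectors)`` frozensets.
    """
    if n_de + n_connectors > net.number_of_nodes():
        raise ValueError("n_de + n_connectors exceeds the number of nodes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    by_degree = sorted(net.nodes(), key=lambda v: (-net.degree(v), v))
    connectors: list = []
    chosen = set()
    for v in by_degree:
        if len(connectors) == n_connectors:
            break
        if any(net.has_edge(v, c) for c in connectors):
            continue
        connectors.append(v)
        chosen.add(v)
    if len(connectors) < n_connectors:
        raise ValueError(
            f"only {len(connectors)} pairwise non-adjacent hubs available, {n_connectors} requested"
        )
    neighborhood = sorted(
        {u for c in connectors for u in net.neighbors(c)} - chosen
    )
    if len(neighborhood) >= n_de:
        de = rng.choice(neighborhood, size=n_de, replace=False)
    else:
        rest = sorted(set(net.nodes()) - chosen - set(neighborhood))
        extra = rng.choice(rest, size=n_de - len(neighborhood), replace=False)
        de = np.concatenate([np.asarray(neighborhood, dtype=object), extra])
    return frozenset(map(str, de)), frozenset(connectors)


def generate_expression(
    genes: Iterable[str],
    de_genes: Iterable[str],
    n_samples: int = 200,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionDataset:
    """Two-class Gaussian expression matrix with mean-shifted DE genes.

    Samples split evenly into class 0 and class 1; DE genes gain a
    ``effect_size * noise_sd`` mean shift in class 1, all other genes have
    equal class means.
    """
    if n_samples < 20:
        raise ValueError("need n_samples >= 20")
    gene_list = sorted(set(genes))
    de = frozenset(de_genes)
    unknown = de - set(gene_list)
    if unknown:
        raise ValueError(f"DE genes absent from the gene universe: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n0 = n_samples // 2
    labels = np.array([0] * n0 + [1] * (n_samples - n0))
    mat = rng.normal(0.0, noise_sd, size=(len(gene_list), n_samples))
    de_rows = np.array([g in de for g in gene_list])
    mat[np.ix_(de_rows, labels == 1)] += effect_size * noise_sd
    samples = [f"S{i:03d}" for i in range(n_samples)]
    values = pd.DataFrame(mat, index=gene_list, columns=samples)
    return ExpressionDataset(values=values, labels=pd.Series(labels, index=samples))


def generate_scenario(params: Optional[ScenarioParams] = None, **overrides) -> SyntheticScenario:
    """Network + planted connectors + DE genes + expression, all from one seed."""
    if params is None:
        params = ScenarioParams(**overrides)
    elif overrides:
        raise ValueError("pass either a ScenarioParams or keyword overrides, not both")
    net = generate_scale_free_network(params.n_nodes, params.edges_per_node, seed=params.seed)
    de, connectors = plant_connectors(net, params.n_de, params.n_connectors, seed=params.seed)
    expression = generate_expression(
        net.nodes(),
        de,
        n_samples=params.n_samples,
        effect_size=params.effect_size,
        noise_sd=params.noise_sd,
        seed=params.seed,
    )
    return SyntheticScenario(
        network=net,
        de_genes=de,
        planted_connectors=connectors,
        expression=expression,
        params=params,
    )


def de_ttest(data: ExpressionDataset) -> pd.Series:
    """Two-sample t-test p-value per gene (harness calibration utility)."""
    y = data.labels.to_numpy()
    a = data.values.to_numpy()[:, y == 0]
    b = data.values.to_numpy()[:, y == 1]
    res = stats.ttest_ind(a, b, axis=1)
    return pd.Series(res.pvalue, index=data.values.index)


@dataclass(frozen=True)
class PermutationTestResult:
    observed_recovered: int
    observed_rate: float
    null_mean_recovered: float
    n_draws: int
    p_value: float


def planted_recovery_test(
    selected: Iterable[str],
    planted: Iterable[str],
    population: Iterable[str],
    n_draws: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Does a selected gene set recover planted genes better than chance?

    Compares ``|selected ∩ planted|`` with the recovery of ``n_draws`` random
    draws of the same size from ``population``; the one-sided permutation
    p-value uses the add-one estimator (1 + #{draw >= observed}) / (n + 1).
    """
    sel = frozenset(selected)
    tgt = frozenset(planted)
    pop = np.array(sorted(set(population)), dtype=object)
    if not tgt:
        raise ValueError("planted set is empty")
    if len(sel) > len(pop):
        raise ValueError("selected set is larger than the population")
    observed = len(sel & tgt)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    tgt_mask = np.array([g in tgt for g in pop])
    hits = np.empty(n_draws, dtype=int)
    for d in range(n_draws):
        idx = rng.choice(len(pop), size=len(sel), replace=False)
        hits[d] = int(tgt_mask[idx].sum())
    p = (1 + int(np.sum(hits >= observed))) / (n_draws + 1)
    return PermutationTestResult(
        observed_recovered=observed,
        observed_rate=observed / len(tgt),
        null_mean_recovered=float(hits.mean()),
        n_draws=n_draws,
        p_value=p,
    )


def write_scenario(scenario: SyntheticScenario, out_dir) -> dict:
    """Write edges.tsv, de.txt, connectors.txt, expr.tsv, labels.tsv; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "edges.tsv",
        "de_genes": out / "de.txt",
        "connectors": out / "connectors.txt",
        "expression": out / "expr.tsv",
        "labels": out / "labels.tsv",
    }
    write_edge_list(scenario.network, paths["network"])
    paths["de_genes"].write_text("".join(f"{g}\n" for g in sorted(scenario.de_genes)))
    paths["connectors"].write_text("".join(f"{g}\n" for g in sorted(scenario.planted_connectors)))
    scenario.expression.to_tsv(paths["expression"], paths["labels"])
    return {k: str(v) for k, v in paths.items()}
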