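"""End-to-end pipeline: load -> LCC -> discover -> overlap/coverage -> evaluate.

Configuration is a flat key=value text file (all keys overridable from the
command line); every output JSON embeds the resolved configuration so a run
can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import sklearn

from .evaluation import ExpressionDataset, evaluate_features, known_marker_coverage, paired_run_comparison
from .overlap_stats import overlap_result
from .ppi_network import (
    largest_connected_component,
    load_edge_list,
    load_gene_list,
    restrict_terminals,
    set_unit_weights,
)
from .stm_discovery import PerturbationConfig, discover_stms, stability_report


def _package_version() -> str:
    from . import __version__

    return __version__


class PipelineStageError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


@dataclass
class PipelineConfig:
    network: str
    de_genes: str
    out_dir: str
    de_genes_b: Optional[str] = None
    expression: Optional[str] = None
    labels: Optional[str] = None
    known_markers: Optional[str] = None
    seed: int = 0
    weight_low: float = 0.99
    weight_high: float = 1.0
    max_iterations: int = 500
    patience: int = 50
    unit_weights: bool = True
    classifier: str = "logistic"
    n_repetitions: int = 100
    n_folds: int = 10
    sif: bool = False

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Parse ``key = value`` lines ('#' comments); keyword overrides win."""
        entries = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key = value, got {line!r}")
            key, _, value = line.partition("=")
            entries[key.strip()] = value.strip()
        entries.update({k: v for k, v in overrides.items() if v is not None})
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(entries) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in entries.items():
            ftype = fields[key].type
            if isinstance(value, str):
                if "int" in ftype:
                    value = int(value)
                elif "float" in ftype:
                    value = float(value)
                elif "bool" in ftype:
                    value = _BOOL[value.lower()]
            kwargs[key] = value
        return cls(**kwargs)

    def validate(self) -> None:
        required = {"network": self.network, "de_genes": self.de_genes}
        optional = {
            "de_genes_b": self.de_genes_b,
            "expression": self.expression,
            "labels": self.labels,
            "known_markers": self.known_markers,
        }
        for name, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p!r}")
        if (self.expression is None) != (self.labels is None):
            raise ValueError("expression and labels must be given together")

    def perturbation(self) -> PerturbationConfig:
        return PerturbationConfig(
            weight_low=self.weight_low,
            weight_high=self.weight_high,
            max_iterations=self.max_iterations,
            patience=self.patience,
            seed=self.seed,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


@_stage("load-network")
def _load_network(config: PipelineConfig) -> nx.Graph:
    net = load_edge_list(config.network, sif=config.sif)
    if config.unit_weights:
        net = set_unit_weights(net)
    return largest_connected_component(net)


@_stage("discover")
def _discover(net, genes, config: PipelineConfig):
    terms = restrict_terminals(net, genes)
    return discover_stms(net, terms, config.perturbation())


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest that is also written to disk."""
    try:
        config.validate()
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("validate-config", exc) from exc

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.as_dict()
    provenance = {
        "config": resolved,
        "config_sha256": hashlib.sha256(
            json.dumps(resolved, sort_keys=True).encode()
        ).hexdigest(),
        "versions": {
            "steinermark": _package_version(),
            "networkx": nx.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    outputs = {}

    lcc = _load_network(config)
    N = lcc.number_of_nodes()

    genes_a = load_gene_list(config.de_genes)
    stms_a = _discover(lcc, genes_a, config)
    stm_json = out / "stm.json"
    _write_json(
        stm_json,
        {
            "genes": sorted(stms_a.genes),
            "n_iterations": stms_a.n_iterations,
            "trace": list(stms_a.per_iteration_new),
            "background_N": N,
            **provenance,
        },
    )
    stm_txt = out / "stm.txt"
    stm_txt.write_text("".join(f"{g}\n" for g in sorted(stms_a.genes)), encoding="utf-8")
    outputs["stm.json"] = str(stm_json)
    outputs["stm.txt"] = str(stm_txt)

    if config.de_genes_b:
        genes_b = load_gene_list(config.de_genes_b)
        stms_b = _discover(lcc, genes_b, config)
        (out / "stm_b.txt").write_text(
            "".join(f"{g}\n" for g in sorted(stms_b.genes)), encoding="utf-8"
        )
        ov = stability_report(stms_a, stms_b, N)
        _write_json(
            out / "overlap.json",
            {**dataclasses.asdict(ov), **provenance},
        )
        outputs["stm_b.txt"] = str(out / "stm_b.txt")
        outputs["overlap.json"] = str(out / "overlap.json")

    if config.known_markers:
        try:
            known = load_gene_list(config.known_markers)
            cov = known_marker_coverage(stms_a.genes, known, N)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("coverage", exc) from exc
        _write_json(
            out / "coverage.json",
            {
                "n_known": cov.n_known,
                "n_covered": cov.n_covered,
                "coverage_percent": cov.coverage_percent,
                "overlap": dataclasses.asdict(cov.overlap),
                **provenance,
            },
        )
        outputs["coverage.json"] = str(out / "coverage.json")

    if config.expression:
        try:
            data = ExpressionDataset.from_tsv(config.expression, config.labels)
            res_stm = evaluate_features(
                data,
                stms_a.genes,
                classifier=config.classifier,
                n_repetitions=config.n_repetitions,
                n_folds=config.n_folds,
                seed=config.seed,
            )
            res_de = evaluate_features(
                data,
                genes_a,
                classifier=config.classifier,
                n_repetitions=config.n_repetitions,
                n_folds=config.n_folds,
                seed=config.seed,
            )
            wins, pval = paired_run_comparison(res_stm, res_de)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("evaluate", exc) from exc
        _write_json(
            out / "classification.json",
            {
                "stm": {"mean_auc": res_stm.mean_auc, "auc_runs": list(res_stm.auc_runs)},
                "de": {"mean_auc": res_de.mean_auc, "auc_runs": list(res_de.auc_runs)},
                "stm_wins_over_de": wins,
                "paired_t_pvalue": pval,
                "classifier": config.classifier,
                **provenance,
            },
        )
        outputs["classification.json"] = str(out / "classification.json")

    manifest = {"outputs": outputs, **provenance}
    _write_json(out / "manifest.json", manifest)
    return manifest
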