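"""Run the full experimental design at configurable scale from one config.

The design crosses clustering methods with contiguity levels: spatially
constrained spectral clustering (SSC) at each δ, contiguity-only spectral
clustering (SC) at each δ, and k-means with no constraint — the classic
nine-cell grid for δ ∈ {1, 4, 8, 16} — then scores every cell (SSW, SSB,
PctML, contiguous-region count), profiles variable importance per region
set, and optionally partitions independent point responses across each
region set.  Every cell is reproducible from the logged seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterConfig, Regionalization, cluster_regions
from .downstream import ImportanceTable, ResponsePartitionReport, partition_response_variance, region_variable_importance
from .evaluate import ClusterQualityReport, evaluate_regionalization
from .io import AdjacencyGraph, ResponseTable, SpatialUnitTable, write_assignment
from .preprocess import FeatureEmbedding, PreprocessConfig, pca_reduce, preprocess_features


@dataclass
class ExperimentConfig:
    k: int = 100
    delta_levels: list[int] = field(default_factory=lambda: [1, 4, 8, 16])
    methods: list[str] = field(default_factory=lambda: ["SSC", "SC", "KMEANS"])
    restarts: int = 1000
    seed: int = 0
    n_trees: int = 500
    eval_space: str = "clean"     # "clean" (standardized variables) or "pca"
    run_importance: bool = True
    out_dir: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("need at least one method")
        bad = set(self.methods) - {"SSC", "SC", "KMEANS"}
        if bad:
            raise ValueError(f"unknown method(s): {sorted(bad)}")
        if any(m in ("SSC", "SC") for m in self.methods) and not self.delta_levels:
            raise ValueError("delta_levels required for SSC/SC")
        if self.eval_space not in ("clean", "pca"):
            raise ValueError("eval_space must be 'clean' or 'pca'")

    def cells(self) -> list[tuple[str, int | None]]:
        out: list[tuple[str, int | None]] = []
        for m in self.methods:
            if m in ("SSC", "SC"):
                out += [(m, d) for d in self.delta_levels]
            else:
                out.append((m, None))
        return out


@dataclass
class ExperimentResult:
    grid: pd.DataFrame
    regionalizations: dict[str, Regionalization]
    reports: dict[str, ClusterQualityReport]
    importances: dict[str, ImportanceTable]
    partitions: dict[str, dict[str, ResponsePartitionReport]]
    embedding: FeatureEmbedding
    clean: SpatialUnitTable
    manifest: dict


def _cell_id(method: str, delta: int | None) -> str:
    return method.lower() if delta is None else f"{method.lower()}_d{delta}"


def run_experiment(table: SpatialUnitTable, graph: AdjacencyGraph,
                   config: ExperimentConfig,
                   responses: ResponseTable | None = None) -> ExperimentResult:
    """Preprocess once, then cluster / evaluate / profile every design cell."""
    clean = preprocess_features(table, graph, config.preprocess)
    embedding = pca_reduce(clean, config.preprocess)
    space = clean.values if config.eval_space == "clean" else embedding.scores

    cells = config.cells()
    seeds = np.random.SeedSequence(config.seed).generate_state(len(cells)) % (2**31 - 1)

    regionalizations: dict[str, Regionalization] = {}
    reports: dict[str, ClusterQualityReport] = {}
    importances: dict[str, ImportanceTable] = {}
    partitions: dict[str, dict[str, ResponsePartitionReport]] = {}
    rows = []
    for (method, delta), cell_seed in zip(cells, seeds):
        cid = _cell_id(method, delta)
        try:
            reg = cluster_regions(embedding, graph, ClusterConfig(
                k=config.k, method=method, delta=delta,
                restarts=config.restarts, seed=int(cell_seed)))
            rep = evaluate_regionalization(reg, space, graph,
                                           eval_delta=delta if delta else 1)
        except Exception as exc:
            raise RuntimeError(f"experiment cell {cid!r} failed: {exc}") from exc
        regionalizations[cid] = reg
        reports[cid] = rep
        row = {"cell": cid, "method": method, "delta": delta, "k": config.k,
               "seed": int(cell_seed), **rep.to_dict()}
        if config.run_importance:
            imp = region_variable_importance(clean, reg, n_trees=config.n_trees,
                                             seed=int(cell_seed), region_set_id=cid)
            importances[cid] = imp
            row["oob_error"] = imp.oob_error
        if responses is not None:
            partitions[cid] = {}
            for resp in responses.response_names:
                part = partition_response_variance(responses, reg, resp)
                partitions[cid][resp] = part
                row[f"among_fraction_{resp}"] = part.among_fraction
                row[f"ssw_{resp}"] = part.ssw
        rows.append(row)

    grid = pd.DataFrame(rows)
    manifest = {
        "k": config.k, "delta_levels": config.delta_levels,
        "methods": config.methods, "restarts": config.restarts,
        "seed": config.seed, "eval_space": config.eval_space,
        "cell_seeds": {c: int(s) for (m, d), s in zip(cells, seeds)
                       for c in [_cell_id(m, d)]},
        "n_units": table.n_units, "n_components": embedding.n_components,
    }
    result = ExperimentResult(grid=grid, regionalizations=regionalizations,
                              reports=reports, importances=importances,
                              partitions=partitions, embedding=embedding,
                              clean=clean, manifest=manifest)
    if config.out_dir:
        _write_experiment(result, Path(config.out_dir))
    return result


def _write_experiment(result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.grid.to_csv(out / "grid.csv", index=False)
    (out / "regions").mkdir(exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)
    for cid, reg in result.regionalizations.items():
        write_assignment(reg, out / "regions" / f"{cid}.csv")
    for cid, rep in result.reports.items():
        with open(out / "reports" / f"{cid}.json", "w") as fh:
            json.dump(rep.to_dict(), fh, indent=2)
    if result.importances:
        (out / "importance").mkdir(exist_ok=True)
        for cid, imp in result.importances.items():
            imp.to_frame().to_csv(out / "importance" / f"{cid}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
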