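"""End-to-end orchestration: interactome → DEGs → network → enrichment.

``run_pipeline`` wires the stages together under a single declarative
configuration, writes every artifact (canonical edge list, DEG table,
annotated GraphML, module membership, global and per-module enrichment
tables) and returns a machine-readable run summary whose counts equal
those obtained by invoking each stage separately on the same inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .deg import DegSelection, read_de_table, select_degs, write_deg_table
from .enrichment import enrich, read_gmt, write_enrichment_table
from .interactome import load_interactome
from .network import (
    ModulePartition,
    SubnetworkResult,
    TargetAnnotation,
    induce_subnetwork,
    overlay_targets,
    read_target_file,
    spectral_partition,
    write_module_table,
    write_network_graphml,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative pipeline configuration; CLI flags override file values."""

    interactome_paths: list[str] = field(default_factory=list)
    interactome_dialects: list[str] | str = "edge_tsv"
    de_table: str = ""
    gene_sets: str = ""
    target_files: dict[str, str] = field(default_factory=dict)
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    min_module_size: int = 5
    min_set: int = 10
    max_set: int = 500
    universe: str = "de_table"  # "de_table" or a path to a symbol list
    vote_threshold: int = 1
    seed: int = 0
    outdir: str = "mirnet_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for p in [*self.interactome_paths, self.de_table, self.gene_sets,
                  *self.target_files.values()]:
            if p and not Path(p).exists():
                raise FileNotFoundError(p)
        if not self.interactome_paths:
            raise ValueError("at least one interactome file is required")
        if not self.de_table:
            raise ValueError("a DE table is required")


@dataclass
class RunSummary:
    """Counts at every stage plus a config echo, serialisable to JSON."""

    version: str = __version__
    config: dict[str, Any] = field(default_factory=dict)
    ci_nodes: int = 0
    ci_edges: int = 0
    de_rows: int = 0
    degs_up: int = 0
    degs_down: int = 0
    induced_nodes: int = 0
    induced_edges: int = 0
    isolated_degs: int = 0
    n_components: int = 0
    lcc_nodes: int = 0
    lcc_edges: int = 0
    n_modules: int = 0
    modularity: float = 0.0
    flagged_targets: int = 0
    tested_terms: int = 0
    significant_terms: int = 0  # p.adjust < 0.05, global enrichment

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


@dataclass
class RunResult:
    """Full in-memory output of one pipeline run."""

    summary: RunSummary
    degs: DegSelection | None = None
    subnetwork: SubnetworkResult | None = None
    partition: ModulePartition | None = None
    annotation: TargetAnnotation | None = None
    global_enrichment: list = field(default_factory=list)
    module_enrichment: dict[int, list] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage in order and write all artifacts to ``outdir``.

    Degenerate intermediate states (no DEGs on the interactome, no
    significant terms) produce warnings and empty downstream artifacts;
    unreadable or unparseable inputs raise.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(config=dataclasses.asdict(config))

    # 1. consolidated interactome
    ci = load_interactome(config.interactome_paths, config.interactome_dialects)
    summary.ci_nodes, summary.ci_edges = ci.n_nodes, ci.n_edges
    ci.to_edge_tsv(outdir / "ci_edges.tsv")

    # 2. DEG selection
    rows = read_de_table(config.de_table)
    summary.de_rows = len(rows)
    degs = select_degs(rows, config.fc_threshold, config.p_threshold)
    summary.degs_up, summary.degs_down = len(degs.up), len(degs.down)
    write_deg_table(degs, rows, outdir / "degs.tsv")

    # 3. induced subnetwork and LCC
    subnet = induce_subnetwork(ci, degs)
    summary.induced_nodes = len(subnet.induced_nodes)
    summary.induced_edges = len(subnet.induced_edges)
    summary.isolated_degs = len(subnet.isolated_degs)
    summary.n_components = subnet.n_components
    summary.lcc_nodes = len(subnet.lcc_nodes)
    summary.lcc_edges = len(subnet.lcc_edges)

    # 4. spectral modules on the LCC
    partition: ModulePartition | None = None
    if len(subnet.lcc_nodes) >= 2:
        partition = spectral_partition(
            subnet.lcc_graph, config.min_module_size, config.seed
        )
        summary.n_modules = partition.n_modules
        summary.modularity = partition.modularity
        write_module_table(partition, outdir / "modules.tsv")

    # 5. miRNA-target overlay
    annotation: TargetAnnotation | None = None
    if config.target_files:
        per_alg: dict[str, set[str]] = {}
        for name, path in config.target_files.items():
            for alg, syms in read_target_file(path, algorithm=name).items():
                per_alg.setdefault(alg, set()).update(syms)
        annotation = overlay_targets(
            subnet.induced_nodes, per_alg, config.vote_threshold
        )
        summary.flagged_targets = len(annotation.predicted_targets)

    if subnet.induced_nodes:
        write_network_graphml(
            subnet, degs, partition, annotation, outdir / "network.graphml"
        )

    # 6. enrichment: global foreground = DEG list; per-module foreground = module
    global_records: list = []
    module_records: dict[int, list] = {}
    if config.gene_sets:
        if config.universe == "de_table":
            universe = [r.gene for r in rows]
        else:
            universe = [
                line.strip()
                for line in Path(config.universe).read_text().splitlines()
                if line.strip()
            ]
        collection = read_gmt(config.gene_sets, universe=universe)
        global_records = enrich(
            degs.genes, collection, config.min_set, config.max_set
        )
        write_enrichment_table(global_records, outdir / "enrichment_global.tsv")
        summary.tested_terms = len(global_records)
        summary.significant_terms = sum(
            1 for r in global_records if r.p_adjust < 0.05
        )
        if partition is not None:
            by_module: dict[int, set[str]] = {}
            for gene, mod in partition.assignment.items():
                by_module.setdefault(mod, set()).add(gene)
            for mod in sorted(by_module):
                recs = enrich(
                    by_module[mod], collection, config.min_set, config.max_set
                )
                module_records[mod] = recs
                write_enrichment_table(
                    recs, outdir / f"enrichment_module_{mod}.tsv"
                )

    summary.to_json(outdir / "run_summary.json")
    return RunResult(
        summary=summary,
        degs=degs,
        subnetwork=subnet,
        partition=partition,
        annotation=annotation,
        global_enrichment=global_records,
        module_enrichment=module_records,
    )
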