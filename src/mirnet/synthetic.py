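"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes,
without any download:

* an interactome with planted modular structure — a stochastic block model
  (SBM) in which within-block gene pairs interact with probability ``p_in``
  and between-block pairs with ``p_out``;
* a differential-expression table over a ~20,000-gene universe with a
  ~19% DE fraction (mirroring a 4,009/20,949 foreground/universe scale),
  heavy-tailed log2 fold changes for true DEGs and uniform null p-values;
* a GMT gene-set collection containing uniform background terms plus
  planted terms that oversample true DEGs by a stated enrichment fold;
* per-algorithm miRNA target-prediction lists sampling network genes
  independently at a fixed rate.

True DEGs are drawn preferentially from the SBM blocks so the induced DEG
subnetwork inherits the planted module structure.  All generators are
deterministic for a fixed seed.  Null p-values are Uniform(0,1) and signal
p-values Beta(0.1, 10) — a minimal model sufficient to exercise
thresholding and FDR behaviour, with no claim of matching the sampling
distribution of any particular DE test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .deg import DeRow
from .enrichment import GeneSetCollection, write_gmt
from .interactome import ConsolidatedInteractome, InteractionRecord, build_consolidated_interactome

_ALGORITHMS = ("targetscan", "pictar", "diana_microt")

# stage tags keep the per-operation random streams independent
_STAGE_GRAPH, _STAGE_DE, _STAGE_SETS, _STAGE_TARGETS = 11, 13, 17, 19


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the scales of the reference analysis: a 20,949-gene
    universe with a ~4,000-gene DE foreground, and four planted 50-gene
    network modules with p_in = 0.30 and p_out = 0.01.
    """

    seed: int = 0
    n_genes: int = 20949
    blocks: Sequence[tuple[int, str]] = (
        (50, "block0"), (50, "block1"), (50, "block2"), (50, "block3"),
    )
    p_in: float = 0.30
    p_out: float = 0.01
    deg_fraction: float = 0.19
    lfc_effect: float = 2.0
    lfc_noise: float = 0.3
    planted_terms: Sequence[tuple[int, float]] = ((100, 5.0), (100, 4.0), (50, 5.0))
    target_fraction: float = 0.3
    n_background_terms: int = 200
    background_size_range: tuple[int, int] = (20, 200)

    def __post_init__(self) -> None:
        if not (0 <= self.p_in <= 1 and 0 <= self.p_out <= 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if any(size <= 0 for size, _ in self.blocks):
            raise ValueError("block sizes must be positive")
        if not 0 <= self.deg_fraction <= 1:
            raise ValueError("deg_fraction must lie in [0, 1]")
        if sum(size for size, _ in self.blocks) > self.n_genes:
            raise ValueError("blocks exceed the gene universe")

    @property
    def genes(self) -> list[str]:
        return [f"G{i:06d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """Planted structure against which pipeline output is scored."""

    block_labels: dict[str, str] = field(default_factory=dict)
    true_degs: set[str] = field(default_factory=set)
    enriched_terms: set[str] = field(default_factory=set)
    target_genes: dict[str, set[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "block_labels": self.block_labels,
            "true_degs": sorted(self.true_degs),
            "enriched_terms": sorted(self.enriched_terms),
            "target_genes": {a: sorted(s) for a, s in self.target_genes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rng(spec: SyntheticSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stage])


def generate_interactome(spec: SyntheticSpec) -> tuple[ConsolidatedInteractome, GroundTruth]:
    """Stochastic-block-model interactome over the first Σ block-size genes.

    Each within-block pair is connected independently with ``p_in``, each
    between-block pair with ``p_out``.  Provenance is labeled "synthetic".
    A parameterisation yielding zero edges is an error.
    """
    rng = _rng(spec, _STAGE_GRAPH)
    genes = spec.genes
    truth = GroundTruth()
    offsets: list[tuple[int, int, str]] = []
    pos = 0
    for size, label in spec.blocks:
        offsets.append((pos, pos + size, label))
        for g in genes[pos:pos + size]:
            truth.block_labels[g] = label
        pos += size

    records: list[InteractionRecord] = []
    for bi, (a0, a1, _) in enumerate(offsets):
        for bj, (b0, b1, _) in enumerate(offsets):
            if bj < bi:
                continue
            if bi == bj:
                iu, ju = np.triu_indices(a1 - a0, k=1)
                mask = rng.random(iu.size) < spec.p_in
                pairs = zip(iu[mask] + a0, ju[mask] + a0)
            else:
                na, nb = a1 - a0, b1 - b0
                mask = rng.random(na * nb) < spec.p_out
                iu, ju = np.unravel_index(np.flatnonzero(mask), (na, nb))
                pairs = zip(iu + a0, ju + b0)
            records.extend(
                InteractionRecord(genes[i], genes[j], "synthetic") for i, j in pairs
            )
    if not records:
        raise ValueError("synthetic spec yields an empty interactome")
    return build_consolidated_interactome(records), truth


def generate_de_table(spec: SyntheticSpec, truth: GroundTruth) -> list[DeRow]:
    """Differential-expression table with planted signal.

    All block genes are true DEGs (so the DEG subnetwork carries the
    planted modules); the remaining DE quota is drawn uniformly from the
    rest of the universe.  True DEGs: log2fc ~ ±Normal(lfc_effect,
    lfc_noise), p ~ Beta(0.1, 10); null genes: log2fc ~ Normal(0,
    lfc_noise), p ~ Uniform(0, 1).  Updates ``truth.true_degs`` in place.
    """
    rng = _rng(spec, _STAGE_DE)
    genes = spec.genes
    block_genes = [g for g in genes if g in truth.block_labels]
    quota = int(round(spec.deg_fraction * spec.n_genes))
    true_degs = set(block_genes[:quota])
    remaining = quota - len(true_degs)
    if remaining > 0:
        pool = np.array([g for g in genes if g not in truth.block_labels])
        extra = rng.choice(pool, size=min(remaining, pool.size), replace=False)
        true_degs.update(extra.tolist())
    truth.true_degs = true_degs

    is_deg = np.array([g in true_degs for g in genes])
    n = spec.n_genes
    signs = rng.choice([-1.0, 1.0], size=n)
    lfc_signal = signs * rng.normal(spec.lfc_effect, spec.lfc_noise, size=n)
    lfc_null = rng.normal(0.0, spec.lfc_noise, size=n)
    p_signal = rng.beta(0.1, 10.0, size=n)
    p_null = rng.uniform(0.0, 1.0, size=n)
    lfc = np.where(is_deg, lfc_signal, lfc_null)
    pval = np.clip(np.where(is_deg, p_signal, p_null), 1e-300, 1.0)
    return [DeRow(g, float(l), float(p)) for g, l, p in zip(genes, lfc, pval)]


def generate_gene_sets(spec: SyntheticSpec, truth: GroundTruth) -> GeneSetCollection:
    """Background terms drawn uniformly; planted terms oversample true DEGs.

    A planted term of size ``s`` with enrichment fold ``f`` contains
    ``min(s, round(f · deg_fraction · s))`` true DEGs, the rest drawn from
    non-DE genes.  Updates ``truth.enriched_terms`` in place.
    """
    rng = _rng(spec, _STAGE_SETS)
    genes = np.array(spec.genes)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    lo, hi = spec.background_size_range
    for i in range(spec.n_background_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        term = f"BG{i:04d}"
        sets[term] = (f"background term {i}", frozenset(members.tolist()))

    deg_arr = np.array(sorted(truth.true_degs))
    null_arr = np.array(sorted(set(spec.genes) - truth.true_degs))
    for i, (size, fold) in enumerate(spec.planted_terms):
        n_deg = min(size, int(round(fold * spec.deg_fraction * size)))
        n_deg = min(n_deg, deg_arr.size)
        members = set(rng.choice(deg_arr, size=n_deg, replace=False).tolist())
        n_null = min(size - n_deg, null_arr.size)
        if n_null > 0:
            members |= set(rng.choice(null_arr, size=n_null, replace=False).tolist())
        term = f"PLANTED{i:02d}"
        sets[term] = (f"planted term {i} (fold {fold:g})", frozenset(members))
        truth.enriched_terms.add(term)
    return GeneSetCollection(sets, frozenset(spec.genes))


def generate_target_lists(spec: SyntheticSpec, truth: GroundTruth) -> dict[str, set[str]]:
    """Three per-algorithm predicted-target lists over the network genes.

    Each algorithm samples network (block) genes independently at
    ``target_fraction``, so pairwise overlaps follow the product rule and
    the union size matches the inclusion–exclusion expectation.  Updates
    ``truth.target_genes`` in place.
    """
    rng = _rng(spec, _STAGE_TARGETS)
    network_genes = np.array(sorted(truth.block_labels))
    out: dict[str, set[str]] = {}
    for alg in _ALGORITHMS:
        mask = rng.random(network_genes.size) < spec.target_fraction
        out[alg] = set(network_genes[mask].tolist())
    truth.target_genes = out
    return out


def write_de_table(rows: Sequence[DeRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tlog2FoldChange\tpvalue\n")
        for r in rows:
            fh.write(f"{r.gene}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\n")


def write_target_lists(targets: dict[str, set[str]], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    paths = {}
    for alg, syms in targets.items():
        p = outdir / f"targets_{alg}.txt"
        p.write_text("\n".join(sorted(syms)) + ("\n" if syms else ""))
        paths[alg] = p
    return paths


def generate_all(spec: SyntheticSpec, outdir: str | Path) -> GroundTruth:
    """Generate every input the pipeline reads, plus a ground-truth JSON.

    Writes ``interactome.tsv``, ``de_table.tsv``, ``gene_sets.gmt``,
    ``targets_<algorithm>.txt`` and ``ground_truth.json`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ci, truth = generate_interactome(spec)
    rows = generate_de_table(spec, truth)
    collection = generate_gene_sets(spec, truth)
    targets = generate_target_lists(spec, truth)
    ci.to_edge_tsv(outdir / "interactome.tsv")
    write_de_table(rows, outdir / "de_table.tsv")
    write_gmt(collection, outdir / "gene_sets.gmt")
    write_target_lists(targets, outdir)
    truth.to_json(outdir / "ground_truth.json")
    return truth
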