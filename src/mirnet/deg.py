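"""Differential-expression table loading and DEG selection.

The pipeline consumes a differential-expression results table (for example
the output of a DESeq2 contrast): one row per gene with a log2 fold change
and an unadjusted p-value.  Genes are called differentially expressed when
they jointly pass a linear fold-change cutoff and a p-value cutoff, with
direction (up/down) given by the sign of the log2 fold change.

The fold-change cutoff is interpreted as a *linear* fold change applied
symmetrically, i.e. a gene passes when ``|log2fc| > log2(fc_threshold)``.
Both inequalities are strict.  The default cutoffs are FC > 1.5 and
p < 0.05; a laxer FC > 1.25 selection is reachable through configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .interactome import normalize_symbol


class DeTableError(ValueError):
    """Fatal condition while reading a differential-expression table."""


@dataclass(frozen=True)
class DeRow:
    gene: str
    log2fc: float
    pvalue: float


@dataclass(frozen=True)
class DegSelection:
    """Thresholded DEG lists with direction labels.

    ``up`` and ``down`` are disjoint by construction (one log2fc per gene
    after deduplication); every member passed both cutoffs strictly.
    """

    up: frozenset[str]
    down: frozenset[str]
    fc_threshold: float
    p_threshold: float

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def direction(self, gene: str) -> str:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        raise KeyError(gene)


def read_de_table(
    path: str | Path,
    *,
    gene_col: str = "gene",
    lfc_col: str = "log2FoldChange",
    p_col: str = "pvalue",
) -> list[DeRow]:
    """Load a DE results table (TSV or CSV, header required).

    Rows with a missing p-value or fold change are dropped with a logged
    count; duplicate gene symbols are resolved by keeping the row with the
    smallest p-value.  Missing any of the three named columns is fatal.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except OSError as exc:
        raise DeTableError(f"cannot read DE table {path}: {exc}") from exc
    missing = [c for c in (gene_col, lfc_col, p_col) if c not in df.columns]
    if missing:
        raise DeTableError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    df = df[[gene_col, lfc_col, p_col]].copy()
    n_before = len(df)
    df = df.dropna()
    df = df[np.isfinite(df[lfc_col]) & np.isfinite(df[p_col])]
    if (dropped := n_before - len(df)):
        logger.warning("%s: dropped %d row(s) with missing values", path, dropped)
    df[gene_col] = df[gene_col].map(normalize_symbol)
    df = df[df[gene_col].notna()]
    # duplicate symbols: keep the smallest p-value
    df = df.sort_values(p_col, kind="stable").drop_duplicates(gene_col, keep="first")
    return [
        DeRow(str(g), float(l), float(p))
        for g, l, p in df[[gene_col, lfc_col, p_col]].itertuples(index=False)
    ]


def select_degs(
    rows: Sequence[DeRow] | Iterable[DeRow],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> DegSelection:
    """Select up/down DEG sets by strict FC and p cutoffs.

    A gene is *up* iff ``log2fc > log2(fc_threshold)`` and
    ``pvalue < p_threshold``; *down* iff ``log2fc < -log2(fc_threshold)``
    and ``pvalue < p_threshold``.
    """
    if not fc_threshold > 1:
        raise ValueError("fc_threshold must be > 1 (linear fold change)")
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must lie in (0, 1]")
    lfc_cut = math.log2(fc_threshold)
    up, down = set(), set()
    for row in rows:
        if row.pvalue < p_threshold:
            if row.log2fc > lfc_cut:
                up.add(row.gene)
            elif row.log2fc < -lfc_cut:
                down.add(row.gene)
    if not up and not down:
        logger.warning(
            "no genes pass FC > %g, p < %g", fc_threshold, p_threshold
        )
    return DegSelection(frozenset(up), frozenset(down), fc_threshold, p_threshold)


def write_deg_table(
    selection: DegSelection, rows: Sequence[DeRow], path: str | Path
) -> None:
    """Export the selection as a TSV: gene, direction, log2fc, pvalue."""
    by_gene = {r.gene: r for r in rows}
    with Path(path).open("w") as fh:
        fh.write("gene\tdirection\tlog2fc\tpvalue\n")
        for gene in sorted(selection.genes):
            r = by_gene[gene]
            fh.write(f"{gene}\t{selection.direction(gene)}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\n")
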