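"""Hypergeometric over-representation analysis with FDR control.

Given a foreground gene list (e.g. the DEG selection, or one network
module), a gene-set collection (GMT) and a background universe, each term
is tested for over-representation with the upper-tail hypergeometric test:
with ``N`` universe genes of which ``K`` carry the annotation, and a
foreground of ``n`` genes containing ``k`` annotated ones,

    pvalue = P(X >= k),   X ~ Hypergeometric(N, K, n).

The printed ``GeneRatio`` is ``k/n`` and ``BgRatio`` is ``K/N``.  P-values
are adjusted across all tested terms by Benjamini–Hochberg step-up, and
Storey q-values are derived from the BH values with a single-λ estimate of
the null proportion π0 (λ = 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .interactome import normalize_symbol

logger = logging.getLogger(__name__)


class GeneSetError(ValueError):
    """Fatal condition while reading a gene-set collection."""


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe used for testing.

    ``sets`` maps a term id to ``(description, member symbols)``.  Sets are
    not forced to be subsets of the universe; intersection happens
    explicitly at test time.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One over-representation result row (one term)."""

    term: str
    description: str
    k: int
    n: int
    K: int
    N: int
    pvalue: float
    p_adjust: float
    qvalue: float

    @property
    def gene_ratio(self) -> str:
        return f"{self.k}/{self.n}"

    @property
    def bg_ratio(self) -> str:
        return f"{self.K}/{self.N}"


def read_gmt(path: str | Path, universe: Iterable[str] = ()) -> GeneSetCollection:
    """Parse a GMT file (term, description, tab-separated members).

    Member symbols are normalized and deduplicated; malformed lines (fewer
    than three fields) are skipped with a logged count; an empty collection
    is fatal.  ``universe`` may be supplied here or attached later.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    n_malformed = 0
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            n_malformed += 1
            continue
        term, desc = fields[0].strip(), fields[1].strip()
        members = frozenset(
            s for s in (normalize_symbol(f) for f in fields[2:]) if s is not None
        )
        if not term or not members:
            n_malformed += 1
            continue
        sets[term] = (desc, members)
    if n_malformed:
        logger.warning("%s: skipped %d malformed GMT line(s)", path, n_malformed)
    if not sets:
        raise GeneSetError(f"no gene sets parsed from {path}")
    return GeneSetCollection(
        sets, frozenset(s for s in (normalize_symbol(u) for u in universe) if s)
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in sorted(collection.sets):
            desc, members = collection.sets[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# the statistics
# ---------------------------------------------------------------------------

def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X ≥ k).

    ``X ~ Hypergeometric(N, K, n)``: ``k`` annotated genes observed in a
    foreground of ``n`` drawn without replacement from a universe of ``N``
    genes of which ``K`` are annotated.  Evaluated through the survival
    function (log-gamma based), never naive factorials.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def estimate_pi0(pvalues: Sequence[float], lam: float = 0.5) -> float:
    """Single-λ estimate of the null proportion: π̂0 = mean(p > λ)/(1 − λ).

    Capped at 1; falls back to 1 for fewer than 10 p-values, where the
    estimator is too unstable to be useful.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 10:
        return 1.0
    return min(1.0, float(np.mean(p > lam)) / (1.0 - lam))


def storey_qvalues(pvalues: Sequence[float]) -> list[float]:
    """Storey q-values: π̂0 times the BH-adjusted p-values.

    q ≤ the corresponding BH value elementwise and is monotone
    non-decreasing in p-value rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    pi0 = estimate_pi0(p)
    return [min(1.0, pi0 * b) for b in bh_adjust(p)]


# ---------------------------------------------------------------------------
# the analysis
# ---------------------------------------------------------------------------

def enrich(
    foreground: Iterable[str],
    collection: GeneSetCollection,
    min_set: int = 10,
    max_set: int = 500,
) -> list[EnrichmentRecord]:
    """Over-representation analysis of a foreground against a collection.

    Foreground genes outside the universe are dropped (logged); each term
    is intersected with the universe and kept when its background count K
    falls in ``[min_set, max_set]``.  Records are BH-adjusted and
    q-valued across all tested terms, and returned sorted by p-value
    ascending with ties broken by term id.
    """
    if min_set > max_set:
        raise ValueError("min_set must be <= max_set")
    universe = set(collection.universe)
    if not universe:
        raise GeneSetError("collection has an empty universe")
    fg_all = {s for s in (normalize_symbol(g) for g in foreground) if s is not None}
    fg = fg_all & universe
    if (outside := len(fg_all) - len(fg)):
        logger.info("dropped %d foreground gene(s) outside the universe", outside)
    if not fg:
        logger.warning("empty foreground after universe intersection")
        return []
    n = len(fg)
    N = len(universe)

    rows: list[tuple[str, str, int, int]] = []
    for term in sorted(collection.sets):
        desc, members = collection.sets[term]
        bg = members & universe
        K = len(bg)
        if not (min_set <= K <= max_set):
            continue
        k = len(fg & bg)
        rows.append((term, desc, k, K))
    if not rows:
        logger.warning("no terms within the [%d, %d] size window", min_set, max_set)
        return []

    pvals = [hypergeometric_pvalue(k, n, K, N) for _, _, k, K in rows]
    padj = bh_adjust(pvals)
    qvals = storey_qvalues(pvals)
    records = [
        EnrichmentRecord(term, desc, k, n, K, N, p, pa, q)
        for (term, desc, k, K), p, pa, q in zip(rows, pvals, padj, qvals)
    ]
    records.sort(key=lambda r: (r.pvalue, r.term))
    return records


def _sci(x: float) -> str:
    """3-significant-digit scientific notation with uppercase E."""
    return f"{x:.2E}"


def write_enrichment_table(records: Sequence[EnrichmentRecord], path: str | Path) -> None:
    """TSV export with the conventional ORA column set plus raw counts."""
    with Path(path).open("w") as fh:
        fh.write(
            "term\tDescription\tGeneRatio\tBgRatio\tpvalue\tp.adjust\tqvalue\t"
            "k\tn\tK\tN\n"
        )
        for r in records:
            fh.write(
                f"{r.term}\t{r.description}\t{r.gene_ratio}\t{r.bg_ratio}\t"
                f"{_sci(r.pvalue)}\t{_sci(r.p_adjust)}\t{_sci(r.qvalue)}\t"
                f"{r.k}\t{r.n}\t{r.K}\t{r.N}\n"
            )
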