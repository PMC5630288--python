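"""Consolidated interactome assembly.

Functional gene/protein interaction catalogues (BioGRID, CORUM, DIP,
InnateDB, IntAct, MatrixDB, MINT, ...) export their content in a variety of
tabular dialects.  This module parses two of them — a plain two-symbol edge
list and a simplified PSI-MITAB layout — and merges any number of such files
into a single undirected, deduplicated, provenance-annotated gene-symbol
graph: the *consolidated interactome* (CI).

Merge semantics: interactions are undirected and untyped; multi-edges
between the same pair collapse to one edge whose provenance is the union of
contributing source labels; self-loops and records with unusable symbols are
dropped.  Gene identifiers are plain uppercased symbols — case-folding is
the cross-species symbol convention used when mouse gene lists are overlaid
on a human interactome (an approximation of orthology, not a real ortholog
map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

#: Placeholder strings that signal an unusable identifier.
_PLACEHOLDERS = {"", "-", "NA", "N/A", "NULL", "NONE"}


class InteractomeError(ValueError):
    """Fatal condition while reading or assembling an interactome."""


def normalize_symbol(raw: str) -> str | None:
    """Normalize a raw gene identifier to an uppercase symbol.

    Returns ``None`` (the invalid marker) for empty strings and common
    placeholder values such as ``"-"`` or ``"NA"``.
    """
    if raw is None:
        return None
    sym = str(raw).strip().upper()
    if sym in _PLACEHOLDERS:
        return None
    return sym


@dataclass(frozen=True)
class InteractionRecord:
    """One raw interaction line: two symbols, a source label, a free-text type."""

    gene_a: str
    gene_b: str
    source: str = "unknown"
    interaction_type: str = ""


def _parse_mitab_field(value: str) -> str | None:
    """Extract a gene name from a MITAB alias-style field.

    Fields look like ``uniprotkb:PTEN(gene name)|uniprotkb:MMAC1(gene name
    synonym)``; the first entry tagged ``(gene name)`` wins, else the first
    entry's value.
    """
    value = value.strip()
    if not value:
        return None
    entries = value.split("|")
    chosen = None
    for entry in entries:
        if "(gene name)" in entry:
            chosen = entry
            break
    if chosen is None:
        chosen = entries[0]
    chosen = chosen.split("(")[0]
    if ":" in chosen:
        chosen = chosen.split(":", 1)[1]
    return normalize_symbol(chosen)


_HEADER_TOKENS = {
    "genea", "geneb", "gene_a", "gene_b", "gene1", "gene2",
    "symbola", "symbolb", "source", "type", "interactor_a", "interactor_b",
}


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields)


def read_interaction_file(
    path: str | Path,
    dialect: str = "edge_tsv",
    *,
    mitab_col_a: int = 4,
    mitab_col_b: int = 5,
    mitab_col_source: int = 12,
    source: str | None = None,
) -> list[InteractionRecord]:
    """Parse one interaction-source file into raw records.

    Parameters
    ----------
    path:
        Tab-separated input file.
    dialect:
        ``"edge_tsv"`` — columns geneA, geneB, [source], [type]; a header
        line is auto-detected and skipped.  ``"mitab_lite"`` — simplified
        PSI-MITAB: interactor symbols taken from the alias columns at
        ``mitab_col_a``/``mitab_col_b`` (0-based; defaults are the
        MITAB 2.5 alias columns), the source database from
        ``mitab_col_source`` when present.
    source:
        Fallback source label for files without a source column; defaults
        to the file stem.

    Malformed lines are skipped with a logged count.  An unreadable file or
    a file yielding zero parseable records is fatal.
    """
    path = Path(path)
    if dialect not in {"edge_tsv", "mitab_lite"}:
        raise InteractomeError(f"unknown interaction dialect: {dialect!r}")
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InteractomeError(f"cannot read interaction file {path}: {exc}") from exc

    default_source = source if source is not None else path.stem
    records: list[InteractionRecord] = []
    n_malformed = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if dialect == "edge_tsv":
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 2:
                n_malformed += 1
                continue
            a, b = fields[0], fields[1]
            src = fields[2].strip() if len(fields) > 2 and fields[2].strip() else default_source
            itype = fields[3].strip() if len(fields) > 3 else ""
        else:  # mitab_lite
            if lineno == 1 and fields and fields[0].lstrip().lower().startswith(("#", "id")):
                continue
            if len(fields) <= max(mitab_col_a, mitab_col_b):
                n_malformed += 1
                continue
            a_sym = _parse_mitab_field(fields[mitab_col_a])
            b_sym = _parse_mitab_field(fields[mitab_col_b])
            if a_sym is None or b_sym is None:
                n_malformed += 1
                continue
            a, b = a_sym, b_sym
            if len(fields) > mitab_col_source and fields[mitab_col_source].strip():
                # e.g. 'psi-mi:"MI:0469"(IntAct)' — the database name sits in
                # the parenthesized label when present
                raw_src = fields[mitab_col_source].split("|")[0].strip()
                if "(" in raw_src and raw_src.endswith(")"):
                    src = raw_src[raw_src.index("(") + 1:-1].strip()
                else:
                    src = raw_src.split(":")[-1].strip()
            else:
                src = default_source
            itype = ""
        if not str(a).strip() or not str(b).strip():
            n_malformed += 1
            continue
        records.append(InteractionRecord(str(a).strip(), str(b).strip(), src, itype))

    if n_malformed:
        logger.warning("%s: skipped %d malformed line(s)", path, n_malformed)
    if not records:
        raise InteractomeError(f"no parseable interaction records in {path}")
    return records


@dataclass
class ConsolidatedInteractome:
    """Undirected, deduplicated gene-symbol graph with per-edge provenance.

    Edges are unordered symbol pairs; ``provenance[(u, v)]`` (with
    ``u < v``) is the set of source-database labels that reported the pair.
    Edge weight is uniformly 1; interaction-type tags are retained only for
    export.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    # -- queries ---------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_key(u, v) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def provenance(self, u: str, v: str) -> set[str]:
        """Source labels for edge (u, v); order of endpoints is irrelevant."""
        if not self.graph.has_edge(u, v):
            raise KeyError(f"no edge between {u!r} and {v!r}")
        return set(self.graph.edges[u, v]["sources"])

    # -- export ----------------------------------------------------------
    def to_edge_tsv(self, path: str | Path) -> None:
        """Write a canonical edge list: sorted pairs, comma-joined provenance."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("geneA\tgeneB\tsource\ttype\n")
            for u, v in sorted(self.edges):
                data = self.graph.edges[u, v]
                fh.write(
                    f"{u}\t{v}\t{','.join(sorted(data['sources']))}\t"
                    f"{','.join(sorted(t for t in data['types'] if t))}\n"
                )

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, data in self.graph.edges(data=True):
            g.add_edge(u, v, sources=",".join(sorted(data["sources"])))
        nx.write_graphml(g, str(path))


def _key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def build_consolidated_interactome(
    records: Iterable[InteractionRecord],
) -> ConsolidatedInteractome:
    """Merge raw records into a consolidated interactome.

    Symbols are normalized; records with an unusable symbol or forming a
    self-loop are dropped; reversed duplicates collapse onto one undirected
    edge whose provenance accumulates every contributing source label.
    An empty surviving edge set is fatal.
    """
    g = nx.Graph()
    n_dropped = 0
    for rec in records:
        a = normalize_symbol(rec.gene_a)
        b = normalize_symbol(rec.gene_b)
        if a is None or b is None or a == b:
            n_dropped += 1
            continue
        if g.has_edge(a, b):
            g.edges[a, b]["sources"].add(rec.source)
            g.edges[a, b]["types"].add(rec.interaction_type)
        else:
            g.add_edge(a, b, sources={rec.source}, types={rec.interaction_type})
    if n_dropped:
        logger.info("dropped %d record(s) (self-loops or invalid symbols)", n_dropped)
    if g.number_of_edges() == 0:
        raise InteractomeError("no edges survive consolidation")
    return ConsolidatedInteractome(g)


def load_interactome(
    paths: Iterable[str | Path],
    dialects: Iterable[str] | str = "edge_tsv",
) -> ConsolidatedInteractome:
    """Read several interaction files and consolidate them in one pass."""
    paths = list(paths)
    if isinstance(dialects, str):
        dialects = [dialects] * len(paths)
    records: list[InteractionRecord] = []
    for p, d in zip(paths, dialects, strict=True):
        records.extend(read_interaction_file(p, d))
    return build_consolidated_interactome(records)


def read_edge_tsv_records(path: str | Path) -> Iterator[InteractionRecord]:
    """Re-read a canonical edge TSV (as written by ``to_edge_tsv``)."""
    for rec in read_interaction_file(path, "edge_tsv"):
        for src in rec.source.split(","):
            yield InteractionRecord(rec.gene_a, rec.gene_b, src, rec.interaction_type)
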