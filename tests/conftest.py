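from __future__ import annotations

from pathlib import Path

import pytest

from mirnet import (
    InteractionRecord,
    build_consolidated_interactome,
)


@pytest.fixture
def write_tsv(tmp_path: Path):
    """Write tab-separated lines to a temp file and return its path."""

    def _write(lines: list[str], name: str = "data.tsv") -> Path:
        p = tmp_path / name
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        return p

    return _write


@pytest.fixture
def small_ci():
    """A tiny consolidated interactome: path A-B-C-D plus isolated pair E-F."""
    records = [
        InteractionRecord("A", "B", "db1"),
        InteractionRecord("B", "C", "db1"),
        InteractionRecord("C", "D", "db2"),
        InteractionRecord("E", "F", "db2"),
    ]
    return build_consolidated_interactome(records)
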