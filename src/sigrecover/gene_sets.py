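"""Literature gene-signature handling: loading, merging, cross-referencing.

Signatures arrive as plain one-symbol-per-line lists or GMT rows. Symbols are
canonicalized case-insensitively (murine literature lists are Title-case
while measured universes are often upper-case), optionally through a
user-supplied two-column ortholog map. Multiple source lists merge into a
composite transcriptome that keeps per-source provenance, and composites are
cross-referenced against the measured (filtered) gene universe to yield
overlap counts in the "size (overlapped)" shape used for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "canonicalize",
    "read_ortholog_map",
    "GeneSet",
    "CompositeTranscriptome",
    "read_gene_list",
    "read_gmt",
    "merge_sets",
    "cross_reference",
    "overlap_report",
]


def canonicalize(symbol: str, ortholog_map: dict[str, str] | None = None) -> str:
    """Canonical form of a gene symbol: stripped, upper-cased, optionally
    remapped through an ortholog table (applied after case folding)."""
    s = symbol.strip().upper()
    if ortholog_map:
        s = ortholog_map.get(s, s)
    return s


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV (source symbol, target symbol) -> canonical mapping dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ConfigurationError(f"ortholog map {path} must have two columns")
    return {
        canonicalize(str(a)): canonicalize(str(b))
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


@dataclass(frozen=True)
class GeneSet:
    """One literature signature: named, provenance-labelled, ordered unique symbols."""

    name: str
    symbols: tuple[str, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise DataError(f"gene set {self.name!r} is empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise DataError(f"gene set {self.name!r} has duplicate symbols after canonicalization")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class CompositeTranscriptome:
    """Union of one or more gene sets with provenance and, after
    cross-referencing, overlap counts against a measured universe."""

    name: str
    members: tuple[GeneSet, ...]
    union_symbols: tuple[str, ...]
    per_set_overlap: dict[str, int] = field(default_factory=dict)
    union_overlap_count: int | None = None
    overlapped_symbols: tuple[str, ...] = ()
    unmatched_symbols: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.union_symbols)

    @property
    def is_cross_referenced(self) -> bool:
        return self.union_overlap_count is not None


def _dedupe(symbols, context: str) -> list[str]:
    seen: dict[str, None] = {}
    n_dup = 0
    for s in symbols:
        if s in seen:
            n_dup += 1
        else:
            seen[s] = None
    if n_dup:
        logger.info("%s: collapsed %d duplicate symbols", context, n_dup)
    return list(seen)


def read_gene_list(
    path,
    name: str | None = None,
    ortholog_map: dict[str, str] | None = None,
    source_label: str = "",
) -> GeneSet:
    """Read one signature from a plain list (one symbol per line) or a
    single-row GMT file. Blank lines are skipped and duplicates collapse to
    their first appearance; both are logged."""
    path = Path(path)
    raw = path.read_text().splitlines()
    lines = [ln for ln in raw if ln.strip()]
    n_blank = len(raw) - len(lines)
    if n_blank:
        logger.info("%s: skipped %d blank lines", path.name, n_blank)
    if not lines:
        raise DataError(f"gene list {path} is empty")
    if any("\t" in ln for ln in lines):
        sets = read_gmt(path, ortholog_map=ortholog_map, source_label=source_label)
        if len(sets) != 1:
            raise DataError(
                f"{path} is a GMT file with {len(sets)} sets; use read_gmt() instead"
            )
        return sets[0] if name is None else replace(sets[0], name=name)
    symbols = _dedupe(
        (canonicalize(ln, ortholog_map) for ln in lines), path.name
    )
    return GeneSet(name=name or path.stem, symbols=tuple(symbols), source_label=source_label)


def read_gmt(
    path,
    ortholog_map: dict[str, str] | None = None,
    source_label: str = "",
) -> list[GeneSet]:
    """Parse a GMT file: tab-separated rows of set name, description, symbols."""
    path = Path(path)
    sets = []
    for i, line in enumerate(path.read_text().splitlines()):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}:{i + 1}: GMT rows need name, description, >=1 symbol")
        name, desc, *symbols = fields
        symbols = _dedupe(
            (canonicalize(s, ortholog_map) for s in symbols if s.strip()),
            f"{path.name}:{name}",
        )
        sets.append(
            GeneSet(name=name, symbols=tuple(symbols), source_label=source_label or desc)
        )
    if not sets:
        raise DataError(f"GMT file {path} contains no sets")
    return sets


def merge_sets(sets: list[GeneSet], name: str) -> CompositeTranscriptome:
    """Merge source signatures into a composite transcriptome.

    The union keeps first-appearance order; symbols shared between sources
    count once, so the composite can be smaller than the sum of its parts.
    Overlap fields stay unset until :func:`cross_reference`.
    """
    if not sets:
        raise DataError(f"composite {name!r} needs at least one member set")
    union = _dedupe((s for gs in sets for s in gs.symbols), f"composite {name}")
    return CompositeTranscriptome(name=name, members=tuple(sets), union_symbols=tuple(union))


def cross_reference(
    ct: CompositeTranscriptome, universe: list[str] | pd.Index
) -> CompositeTranscriptome:
    """Count composite and per-source overlap with a measured gene universe.

    The universe must be canonicalized the same way as the signatures (the
    filtered expression matrix's gene ids). Idempotent for a fixed universe.
    """
    uni = set(universe)
    if not uni:
        raise DataError("cross_reference: empty gene universe")
    overlapped = tuple(s for s in ct.union_symbols if s in uni)
    unmatched = tuple(s for s in ct.union_symbols if s not in uni)
    per_set = {gs.name: sum(1 for s in gs.symbols if s in uni) for gs in ct.members}
    logger.info(
        "composite %s: %d/%d symbols in universe", ct.name, len(overlapped), len(ct)
    )
    return replace(
        ct,
        per_set_overlap=per_set,
        union_overlap_count=len(overlapped),
        overlapped_symbols=overlapped,
        unmatched_symbols=unmatched,
    )


def overlap_report(composites: list[CompositeTranscriptome]) -> pd.DataFrame:
    """Tabular 'size (overlapped)' report: one row per composite, then one
    indented row per member source."""
    rows = []
    for ct in composites:
        if not ct.is_cross_referenced:
            raise DataError(f"composite {ct.name!r} has not been cross-referenced")
        rows.append(
            {
                "transcriptome": ct.name,
                "level": "composite",
                "size": len(ct),
                "overlapped": ct.union_overlap_count,
                "size_overlapped": f"{len(ct)} ({ct.union_overlap_count})",
            }
        )
        for gs in ct.members:
            rows.append(
                {
                    "transcriptome": f"{ct.name}/{gs.name}",
                    "level": "member",
                    "size": len(gs),
                    "overlapped": ct.per_set_overlap[gs.name],
                    "size_overlapped": f"{len(gs)} ({ct.per_set_overlap[gs.name]})",
                }
            )
    return pd.DataFrame(rows)
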