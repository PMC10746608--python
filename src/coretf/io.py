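"""Readers and writers for the symbol-level artifacts of the pipeline.

All inputs are plain text: gene lists (one symbol per line, or a
single-column TSV with an optional header), gene-set libraries in the
Enrichr/MSigDB GMT dialect, TF catalogs with optional alias maps, and
two-column interaction (edge) tables.  Gene symbols are normalized on
ingestion: surrounding and internal whitespace removed, uppercased.  No
automatic alias resolution happens here — published candidate lists mix
naming dialects (e.g. "OCT4" vs "POU5F1"), and silently renaming would
manufacture or destroy overlaps; an explicit alias map on the TF catalog
is the only renaming mechanism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

logger = logging.getLogger("coretf")

__all__ = [
    "normalize_symbol",
    "GeneList",
    "GeneSet",
    "GeneSetLibrary",
    "TFCatalog",
    "InteractionTable",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_tf_catalog",
    "read_alias_map",
    "read_interactions",
    "write_interactions",
    "write_enrichment_table",
    "read_enrichment_table",
    "write_report",
]

#: tokens that mark a first line as a column header rather than a symbol
_HEADER_TOKENS = {
    "GENE", "GENES", "SYMBOL", "SYMBOLS", "GENESYMBOL", "GENE_SYMBOL",
    "GENEID", "GENE_ID", "ID", "NAME", "TF", "TFS",
}


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: whitespace stripped everywhere, uppercase.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    return "".join(symbol.split()).upper()


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of normalized gene symbols."""

    label: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"GeneList {self.label!r} contains duplicate symbols")
        if any(not s for s in self.symbols):
            raise ValueError(f"GeneList {self.label!r} contains empty symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    @property
    def symbol_set(self) -> frozenset[str]:
        return frozenset(self.symbols)

    @classmethod
    def from_iterable(cls, symbols: Iterable[str], label: str = "") -> "GeneList":
        """Build a GeneList, normalizing and deduplicating while preserving order."""
        seen: dict[str, None] = {}
        n_dup = 0
        for raw in symbols:
            sym = normalize_symbol(raw)
            if not sym:
                continue
            if sym in seen:
                n_dup += 1
            else:
                seen[sym] = None
        if n_dup:
            logger.info("gene list %r: removed %d duplicate symbols", label, n_dup)
        return cls(label=label, symbols=tuple(seen))


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line): unique normalized members.

    ``tf_symbol`` is populated for TF-target (ChEA-style) libraries, where
    the set name embeds the assayed TF followed by experiment metadata.
    """

    name: str
    description: str
    members: frozenset[str]
    tf_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if any(not m for m in self.members):
            raise ValueError(f"gene set {self.name!r} contains empty members")
        if self.tf_symbol is not None and not self.tf_symbol:
            raise ValueError(f"gene set {self.name!r}: tf_symbol must be non-empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneSetLibrary:
    """A collection of gene sets over a declared background universe of size N.

    Only the size of the universe is required (the canonical assumption is
    roughly 22,000 protein-coding genes); an explicit universe is optional
    and, when present, constrains set membership.
    """

    library_id: str
    sets: tuple[GeneSet, ...]
    background_size: int
    background_universe: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.background_size <= 0:
            raise ValueError("background_size must be positive")
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"library {self.library_id!r}: duplicate set names {dup}")
        biggest = max((len(s) for s in self.sets), default=0)
        if biggest > self.background_size:
            raise ValueError(
                f"library {self.library_id!r}: a set of size {biggest} exceeds "
                f"background_size {self.background_size}"
            )
        if self.background_universe is not None:
            if len(self.background_universe) != self.background_size:
                raise ValueError(
                    f"library {self.library_id!r}: explicit universe has "
                    f"{len(self.background_universe)} symbols but background_size "
                    f"is {self.background_size}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def set_names(self) -> list[str]:
        return [s.name for s in self.sets]

    def sets_by_tf(self) -> dict[str, list[GeneSet]]:
        """Group sets by their annotated TF symbol (sets without one are skipped)."""
        out: dict[str, list[GeneSet]] = {}
        for s in self.sets:
            if s.tf_symbol is not None:
                out.setdefault(s.tf_symbol, []).append(s)
        return out


@dataclass(frozen=True)
class TFCatalog:
    """A census of transcription-factor symbols with an optional alias map."""

    symbols: frozenset[str]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for alias, canonical in self.aliases.items():
            if canonical not in self.symbols:
                raise ValueError(
                    f"alias {alias!r} maps to {canonical!r}, absent from catalog"
                )
            if alias in self.symbols and alias != canonical:
                raise ValueError(
                    f"alias {alias!r} collides with a distinct catalog symbol"
                )

    def __len__(self) -> int:
        return len(self.symbols)

    def resolve(self, symbol: str) -> str:
        """Map a (possibly aliased) symbol to its canonical catalog form."""
        sym = normalize_symbol(symbol)
        return self.aliases.get(sym, sym)

    def __contains__(self, symbol: str) -> bool:
        return self.resolve(symbol) in self.symbols


@dataclass(frozen=True)
class InteractionTable:
    """Undirected interaction edges, canonicalized and deduplicated.

    Each unordered symbol pair is stored once as a lexicographically sorted
    tuple; duplicates (in either orientation) are collapsed with their
    multiplicity recorded.  Self-pairs are permitted.
    """

    edges: Mapping[tuple[str, str], int]
    sources: Mapping[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError(f"edge {(a, b)} is not in canonical sorted order")

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def partners_of(self, symbol: str) -> set[str]:
        """Distinct partners of ``symbol`` (includes the symbol itself for a self-pair)."""
        sym = normalize_symbol(symbol)
        out: set[str] = set()
        for a, b in self.edges:
            if a == sym:
                out.add(b)
            elif b == sym:
                out.add(a)
        return out

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        source: Optional[str] = None,
    ) -> "InteractionTable":
        edges: dict[tuple[str, str], int] = {}
        sources: dict[tuple[str, str], tuple[str, ...]] = {}
        for a, b in pairs:
            key = _canonical_pair(a, b)
            if key is None:
                continue
            edges[key] = edges.get(key, 0) + 1
            if source is not None:
                sources[key] = (source,)
        return cls(edges=edges, sources=sources)


def _canonical_pair(a: str, b: str) -> Optional[tuple[str, str]]:
    na, nb = normalize_symbol(a), normalize_symbol(b)
    if not na or not nb:
        return None
    return (na, nb) if na <= nb else (nb, na)


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path, label: Optional[str] = None) -> GeneList:
    """Read a gene list: one symbol per line or the first column of a TSV.

    Blank lines and ``#`` comments are skipped.  A first line whose token is a
    recognizable column header (``gene``, ``symbol``, ``id``, ...) is treated
    as a header.  Duplicates after normalization are removed (count logged).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    tokens: list[str] = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens.append(line.split("\t")[0].strip())
    if tokens and normalize_symbol(tokens[0]) in _HEADER_TOKENS:
        tokens = tokens[1:]
    result = GeneList.from_iterable(tokens, label=label if label is not None else path.stem)
    if len(result) == 0:
        raise ValueError(f"{path}: zero symbols after filtering")
    return result


def write_gene_list(genes: GeneList | Sequence[str], path: str | Path) -> None:
    symbols = list(genes.symbols) if isinstance(genes, GeneList) else [normalize_symbol(s) for s in genes]
    Path(path).write_text("".join(f"{s}\n" for s in symbols))


# ---------------------------------------------------------------------------
# GMT libraries
# ---------------------------------------------------------------------------

def parse_tf_name(set_name: str, dialect: str = "whitespace") -> str:
    """Extract the TF symbol from a ChEA-style set name.

    Set names embed the assayed TF followed by experiment metadata (PMID,
    cell type, species); the TF is the first token.  ``dialect`` selects the
    delimiter: ``"whitespace"`` (default) or ``"underscore"``.
    """
    if dialect == "whitespace":
        token = set_name.split()[0] if set_name.split() else ""
    elif dialect == "underscore":
        token = set_name.split("_")[0]
    else:
        raise ValueError(f"unknown TF-name dialect {dialect!r}")
    return normalize_symbol(token)


def read_gmt(
    path: str | Path,
    library_id: Optional[str] = None,
    background_size: int = 22000,
    parse_tf_names: bool = False,
    tf_name_dialect: str = "whitespace",
    background_universe: Optional[Iterable[str]] = None,
) -> GeneSetLibrary:
    """Read a GMT library (Enrichr/MSigDB dialect).

    Each tab-separated line is ``name<TAB>description<TAB>member...``; the
    description field is never a member, and trailing empty fields are
    tolerated.  Duplicate members within a line are collapsed; duplicate set
    names across lines are an error.  Members outside a supplied explicit
    universe are dropped with a warning (public libraries routinely contain
    retired symbols).
    """
    path = Path(path)
    lib_id = library_id if library_id is not None else path.stem
    universe = (
        frozenset(normalize_symbol(s) for s in background_universe)
        if background_universe is not None
        else None
    )
    sets: list[GeneSet] = []
    n_dropped = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
            )
        name = fields[0].strip()
        description = fields[1].strip()
        members_list = [normalize_symbol(m) for m in fields[2:]]
        members = frozenset(m for m in members_list if m)
        if universe is not None:
            kept = members & universe
            n_dropped += len(members) - len(kept)
            members = kept
        tf_symbol = parse_tf_name(name, tf_name_dialect) if parse_tf_names else None
        sets.append(
            GeneSet(name=name, description=description, members=members, tf_symbol=tf_symbol or None)
        )
    if n_dropped:
        logger.warning(
            "library %r: dropped %d members outside the explicit universe", lib_id, n_dropped
        )
    return GeneSetLibrary(
        library_id=lib_id,
        sets=tuple(sets),
        background_size=background_size,
        background_universe=universe,
    )


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library in GMT format (members sorted for determinism)."""
    with open(path, "w") as fh:
        for s in library.sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# TF catalog
# ---------------------------------------------------------------------------

def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping alias -> canonical symbol."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: alias line needs 2 columns")
        out[normalize_symbol(fields[0])] = normalize_symbol(fields[1])
    return out


def read_tf_catalog(path: str | Path, alias_path: Optional[str | Path] = None) -> TFCatalog:
    """Read a TF census (gene-list format) plus an optional alias map."""
    symbols = read_gene_list(path, label="tf_catalog").symbol_set
    aliases = read_alias_map(alias_path) if alias_path is not None else {}
    return TFCatalog(symbols=symbols, aliases=aliases)


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

_INTERACTION_HEADER_HINTS = {
    "SYMBOL", "SYMBOLA", "SYMBOLB", "INTERACTOR", "INTERACTORA", "INTERACTORB",
    "GENEA", "GENEB", "PARTNER", "SOURCE", "OFFICIALSYMBOLA", "OFFICIALSYMBOLB",
}


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a >=2-column TSV of symbol pairs into a canonical undirected table.

    Pairs are normalized to lexicographically sorted unordered form, so the
    result is independent of row order and of which symbol sits in which
    column.  Rows with a missing symbol are skipped (count logged).  A
    ``source`` column, when named in a header, is carried along.
    """
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")]
    source_col: Optional[int] = None
    if lines:
        first = [normalize_symbol(f) for f in lines[0].split("\t")]
        if any(tok in _INTERACTION_HEADER_HINTS for tok in first):
            if "SOURCE" in first:
                source_col = first.index("SOURCE")
            lines = lines[1:]
    edges: dict[tuple[str, str], int] = {}
    sources: dict[tuple[str, str], set[str]] = {}
    n_skipped = 0
    for raw in lines:
        fields = raw.split("\t")
        if len(fields) < 2:
            n_skipped += 1
            continue
        key = _canonical_pair(fields[0], fields[1])
        if key is None:
            n_skipped += 1
            continue
        edges[key] = edges.get(key, 0) + 1
        if source_col is not None and len(fields) > source_col and fields[source_col].strip():
            sources.setdefault(key, set()).add(fields[source_col].strip())
    if n_skipped:
        logger.info("%s: skipped %d rows with missing symbols", path, n_skipped)
    return InteractionTable(
        edges=edges,
        sources={k: tuple(sorted(v)) for k, v in sources.items()},
    )


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol_a\tsymbol_b\tmultiplicity\tsource\n")
        for (a, b) in table.pairs():
            src = ";".join(table.sources.get((a, b), ()))
            fh.write(f"{a}\t{b}\t{table.edges[(a, b)]}\t{src}\n")


# ---------------------------------------------------------------------------
# result tables and reports
# ---------------------------------------------------------------------------

ENRICHMENT_COLUMNS = (
    "library_id", "set_name", "k", "K", "n", "N",
    "odds_ratio", "p_raw", "p_adj", "overlap_members",
)


def write_enrichment_table(table, path: str | Path) -> None:
    """Write an EnrichmentTable as TSV with a fixed column order.

    The first line is a ``#``-prefixed metadata comment carrying the query
    label and threshold so the file round-trips losslessly.
    """
    with open(path, "w") as fh:
        fh.write(f"# query_label={table.query_label}\tthreshold={table.threshold!r}\n")
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for r in table.records:
            fh.write(
                "\t".join([
                    r.library_id,
                    r.set_name,
                    str(r.k), str(r.K), str(r.n), str(r.N),
                    f"{r.odds_ratio:.6g}",
                    f"{r.p_raw:.6e}",
                    f"{r.p_adj:.6e}",
                    ";".join(r.overlap_members),
                ]) + "\n"
            )


def read_enrichment_table(path: str | Path):
    """Read back a TSV written by :func:`write_enrichment_table`."""
    from .enrichment import EnrichmentRecord, EnrichmentTable

    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing metadata comment line")
    meta = dict(item.split("=", 1) for item in lines[0][1:].strip().split("\t"))
    records = []
    for raw in lines[2:]:
        f = raw.split("\t")
        records.append(
            EnrichmentRecord(
                library_id=f[0], set_name=f[1],
                k=int(f[2]), K=int(f[3]), n=int(f[4]), N=int(f[5]),
                odds_ratio=float(f[6]), p_raw=float(f[7]), p_adj=float(f[8]),
                overlap_members=tuple(f[9].split(";")) if f[9] else (),
            )
        )
    return EnrichmentTable(
        records=tuple(records),
        threshold=float(meta["threshold"]),
        query_label=meta["query_label"],
        presorted=True,
    )


def write_report(report, json_path: str | Path, tsv_path: Optional[str | Path] = None) -> None:
    """Persist a CoreTFReport as JSON (full) and optionally a TSV evidence mirror."""
    payload = report.to_json_dict()
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            cols = ("tf", "in_selected_list", "in_core", "best_set_name",
                    "k", "K", "n", "N", "p_raw", "p_adj", "n_experiments")
            fh.write("\t".join(cols) + "\n")
            for ev in payload["evidence"]:
                fh.write("\t".join(str(ev.get(c, "")) for c in cols) + "\n")
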