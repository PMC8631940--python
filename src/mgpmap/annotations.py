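"""Gene-set resolution from flat-file ontology and gene-catalog snapshots.

Process-centered MGP analyses start from a named biological process: the
ontology map links process terms (GO ids) to annotated gene symbols, and
the gene catalog supplies genomic intervals for each gene. Only direct
term-to-gene annotations are used; the ontology graph is never traversed.
Coordinates are 1-based inclusive (Ensembl convention).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed catalog/ontology input or an unresolvable gene set."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene with the interval of its longest transcript.

    ``transcript_length_bp`` is ``end_bp - start_bp + 1`` for the retained
    transcript (both ends inclusive).
    """

    symbol: str
    chromosome: str
    start_bp: int
    end_bp: int
    transcript_length_bp: int = field(default=0)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise AnnotationError(
                f"gene {self.symbol}: start {self.start_bp} > end {self.end_bp}"
            )
        if self.transcript_length_bp == 0:
            object.__setattr__(
                self, "transcript_length_bp", self.end_bp - self.start_bp + 1
            )

    @property
    def center_bp(self) -> int:
        """Midpoint of the gene interval, rounded down."""
        return (self.start_bp + self.end_bp) // 2


@dataclass
class OntologyMap:
    """Direct (go_id, term, gene_symbol) annotations."""

    entries: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        self.term_names: dict[str, str] = {}
        self.term_genes: dict[str, list[str]] = {}
        for go_id, term, gene in self.entries:
            key = (go_id, gene)
            if key in seen:
                raise AnnotationError(f"duplicate annotation {key}")
            seen.add(key)
            prev = self.term_names.setdefault(go_id, term)
            if prev != term:
                raise AnnotationError(
                    f"{go_id} has conflicting names {prev!r} / {term!r}"
                )
            self.term_genes.setdefault(go_id, []).append(gene)

    def genes_for(self, go_id: str) -> list[str]:
        if go_id not in self.term_genes:
            raise KeyError(f"unknown GO id {go_id}")
        return list(self.term_genes[go_id])


@dataclass
class GeneSet:
    """Genes resolved for a process query, deduplicated by symbol."""

    query: str
    go_ids: list[str]
    genes: list[GeneRecord]

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def __len__(self) -> int:
        return len(self.genes)


def _open_text(path) -> io.TextIOBase:
    # gzip-transparent: sniff the two magic bytes rather than trusting suffix
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def load_gene_catalog(path) -> list[GeneRecord]:
    """Read a transcript-level catalog and retain one record per gene.

    Expects 6 tab-separated columns: gene symbol, transcript id,
    chromosome, start (1-based), end (inclusive), strand. Lines starting
    with ``#`` are ignored. Among a gene's transcripts the one maximizing
    ``end - start`` is retained; ties break toward the smallest start.
    A symbol mapping to more than one chromosome is rejected: gene
    identity is keyed on symbol throughout the package.
    """
    best: dict[str, tuple[int, int, str]] = {}  # symbol -> (-span, start, chrom) best key
    records: dict[str, GeneRecord] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            symbol, _transcript, chrom, start_s, end_s, _strand = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start > end:
                raise AnnotationError(
                    f"{path}: line {lineno}: start {start} > end {end} "
                    f"for gene {symbol}"
                )
            if symbol in records and records[symbol].chromosome != chrom:
                raise AnnotationError(
                    f"gene symbol {symbol} maps to multiple chromosomes "
                    f"({records[symbol].chromosome}, {chrom})"
                )
            key = (-(end - start), start)
            if symbol not in best or key < best[symbol][:2]:
                best[symbol] = (*key, chrom)
                records[symbol] = GeneRecord(symbol, chrom, start, end)
    if not records:
        raise AnnotationError(f"{path}: no gene records")
    return sorted(records.values(), key=lambda g: (g.chromosome, g.start_bp, g.symbol))


def load_ontology(path) -> OntologyMap:
    """Read a 3-column TSV (go_id, term, gene_symbol) ontology snapshot."""
    entries: list[tuple[str, str, str]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns"
                )
            entries.append((parts[0], parts[1], parts[2]))
    if not entries:
        raise AnnotationError(f"{path}: empty ontology")
    return OntologyMap(entries)


def filter_terms(query: str, ontology: OntologyMap) -> list[tuple[str, str, int]]:
    """Terms whose name contains any ``|``-separated alternative.

    Matching is case-insensitive substring; ``|`` is a union (OR)
    operator over alternatives. Returns (go_id, term, n_genes) sorted by
    go_id; an empty result is not an error.
    """
    if not query:
        raise AnnotationError("empty query")
    tokens = [t.strip().lower() for t in query.split("|") if t.strip()]
    if not tokens:
        raise AnnotationError(f"query {query!r} has no usable alternatives")
    out = []
    for go_id in sorted(ontology.term_names):
        term = ontology.term_names[go_id]
        low = term.lower()
        if any(tok in low for tok in tokens):
            out.append((go_id, term, len(ontology.term_genes[go_id])))
    return out


def resolve_gene_set(
    go_ids: list[str],
    ontology: OntologyMap,
    catalog: list[GeneRecord],
    query: str | None = None,
) -> GeneSet:
    """Union of annotated genes across terms, matched to catalog intervals.

    Genes annotated to a term but absent from the catalog are dropped with
    a logged warning; an empty resolved set is an error. The result is
    order-invariant in ``go_ids`` and deduplicated by symbol.
    """
    by_symbol = {g.symbol: g for g in catalog}
    symbols: set[str] = set()
    for go_id in go_ids:
        symbols.update(ontology.genes_for(go_id))
    found = sorted(s for s in symbols if s in by_symbol)
    missing = sorted(symbols - set(found))
    if missing:
        logger.warning(
            "%d gene(s) annotated but absent from catalog: %s",
            len(missing),
            ", ".join(missing),
        )
    if not found:
        raise AnnotationError("no mappable genes for " + ", ".join(sorted(go_ids)))
    genes = sorted(
        (by_symbol[s] for s in found),
        key=lambda g: (g.chromosome, g.start_bp, g.symbol),
    )
    return GeneSet(
        query=query if query is not None else "|".join(sorted(set(go_ids))),
        go_ids=sorted(set(go_ids)),
        genes=genes,
    )
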