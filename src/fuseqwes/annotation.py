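"""Gene-model annotation: GTF parsing and interval-indexed gene lookup.

Coordinates are 1-based inclusive throughout (the GTF convention); SAM/BAM
0-based positions are converted at the read-extraction boundary so the whole
pipeline speaks one convention.

Gene assignment downstream uses the full gene span (introns included): exome
and panel captures routinely produce reads in intronic flanks, and fusion
breakpoints in DNA fall in introns more often than in exons.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

#: biotype attribute keys accepted, in priority order (GTF dialect drift)
_BIOTYPE_KEYS = ("gene_biotype", "gene_type")


class AnnotationError(Exception):
    """Raised for unresolvable annotation problems (unknown ids, bad queries)."""


@dataclass(frozen=True)
class Exon:
    transcript_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    number: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"exon start > end: {self}")


@dataclass(eq=False)  # identity hash: one instance per annotation
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list[Exon] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    def spliced_length(self) -> int:
        return sum(e.end - e.start + 1 for e in self.exons)


@dataclass(eq=False)  # identity hash: one instance per annotation
class Gene:
    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "unknown"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene start > end: {self.gene_id}")


class GenomeAnnotation:
    """Genes, transcripts and exons with an interval index for gene lookup."""

    def __init__(self, genes: Iterable[Gene], transcripts: Iterable[Transcript]):
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        self.transcripts: dict[str, Transcript] = {
            t.transcript_id: t for t in transcripts
        }
        for t in self.transcripts.values():
            if t.gene_id not in self.genes:
                raise AnnotationError(
                    f"transcript {t.transcript_id} references unknown gene {t.gene_id}"
                )
        self._by_gene: dict[str, list[Transcript]] = {}
        for t in self.transcripts.values():
            self._by_gene.setdefault(t.gene_id, []).append(t)
        self._index: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            # interval tree is half-open; +1 makes [start, end] inclusive
            self._index.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end + 1, g.gene_id
            )

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def n_exons(self) -> int:
        return sum(len(t.exons) for t in self.transcripts.values())

    def genes_overlapping(self, chrom: str, start: int, end: int) -> set[Gene]:
        """All genes whose [start, end] span intersects the 1-based query."""
        if start > end:
            raise ValueError(f"query start {start} > end {end}")
        tree = self._index.get(chrom)
        if tree is None:
            return set()
        return {self.genes[iv.data] for iv in tree.overlap(start, end + 1)}

    def gene_ids_overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        return {g.gene_id for g in self.genes_overlapping(chrom, start, end)}

    def transcripts_of(self, gene_id: str) -> set[Transcript]:
        if gene_id not in self.genes:
            raise AnnotationError(f"unknown gene_id: {gene_id}")
        return set(self._by_gene.get(gene_id, []))

    def gene(self, gene_id: str) -> Gene:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise AnnotationError(f"unknown gene_id: {gene_id}") from None


def _open_maybe_gzip(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(path: str | Path) -> GenomeAnnotation:
    """Parse gene/transcript/exon records from a GTF file.

    Gene spans come from ``gene`` feature lines when present, otherwise they
    are inferred as the min/max over that gene's exons.  Exon lines missing a
    gene_id are skipped with a warning naming the offending line.
    """
    genes: dict[str, Gene] = {}
    tx: dict[str, Transcript] = {}
    exon_bounds: dict[str, tuple[str, int, int, str, str]] = {}  # inferred gene info

    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                log.warning("%s:%d: expected 9 columns, got %d — skipped",
                            path, lineno, len(cols))
                continue
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = cols
            start, end = int(start_s), int(end_s)
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("gene_id")

            if feature == "gene":
                if gene_id is None:
                    log.warning("%s:%d: gene line missing gene_id — skipped", path, lineno)
                    continue
                biotype = next(
                    (attrs[k] for k in _BIOTYPE_KEYS if k in attrs), "unknown"
                )
                genes[gene_id] = Gene(
                    gene_id=gene_id,
                    name=attrs.get("gene_name", gene_id),
                    chrom=chrom, start=start, end=end,
                    strand=strand, biotype=biotype,
                )
            elif feature == "exon":
                if gene_id is None:
                    log.warning("%s:%d: exon line missing gene_id — skipped", path, lineno)
                    continue
                tx_id = attrs.get("transcript_id")
                if tx_id is None:
                    log.warning("%s:%d: exon line missing transcript_id — skipped",
                                path, lineno)
                    continue
                t = tx.setdefault(tx_id, Transcript(tx_id, gene_id))
                number = int(attrs.get("exon_number", len(t.exons) + 1))
                t.exons.append(Exon(tx_id, chrom, start, end, number))
                # track inferred span for genes lacking a "gene" feature line
                biotype = next(
                    (attrs[k] for k in _BIOTYPE_KEYS if k in attrs), "unknown"
                )
                if gene_id in exon_bounds:
                    c, s, e, st, bt = exon_bounds[gene_id]
                    exon_bounds[gene_id] = (
                        c, min(s, start), max(e, end), st,
                        bt if bt != "unknown" else biotype,
                    )
                else:
                    exon_bounds[gene_id] = (chrom, start, end, strand, biotype)
            # transcript and other feature lines carry no extra information we use

    for gene_id, (chrom, start, end, strand, biotype) in exon_bounds.items():
        if gene_id not in genes:
            genes[gene_id] = Gene(gene_id, gene_id, chrom, start, end, strand, biotype)

    for t in tx.values():
        t.exons.sort(key=lambda e: e.start)

    return GenomeAnnotation(genes.values(), tx.values())


def write_gtf(ann: GenomeAnnotation, path: str | Path) -> None:
    """Serialize an annotation back to GTF (round-trip partner of parse_gtf)."""
    with open(path, "w") as fh:
        for g in sorted(ann.genes.values(), key=lambda g: (g.chrom, g.start)):
            attrs = (f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                     f'gene_biotype "{g.biotype}";')
            fh.write("\t".join([g.chrom, "fuseqwes", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")
            for t in sorted(ann.transcripts_of(g.gene_id),
                            key=lambda t: t.transcript_id):
                for e in t.exons:
                    attrs = (f'gene_id "{g.gene_id}"; '
                             f'transcript_id "{t.transcript_id}"; '
                             f'exon_number "{e.number}"; '
                             f'gene_name "{g.name}"; gene_biotype "{g.biotype}";')
                    fh.write("\t".join([e.chrom, "fuseqwes", "exon", str(e.start),
                                        str(e.end), ".", g.strand, ".", attrs]) + "\n")


def genes_overlapping(ann: GenomeAnnotation, chrom: str, start: int, end: int) -> set[Gene]:
    """Module-level alias for :meth:`GenomeAnnotation.genes_overlapping`."""
    return ann.genes_overlapping(chrom, start, end)


def transcripts_of(ann: GenomeAnnotation, gene_id: str) -> set[Transcript]:
    """Module-level alias for :meth:`GenomeAnnotation.transcripts_of`."""
    return ann.transcripts_of(gene_id)
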