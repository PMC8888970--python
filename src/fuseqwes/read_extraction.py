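"""Evidence extraction from DNA alignments.

Streams SAM/BAM records, applies the MAPQ gate (default >= 30, both mates and
supplementary segments), and classifies read pairs into

* **discordant pairs** — mates assigned to disjoint gene sets, spanning (not
  crossing) a putative fusion junction;
* **split reads** — a soft-clipped primary alignment plus a supplementary
  alignment placing the clipped portion in a second gene, directly covering
  the junction.

Discordance is defined by gene-assignment disjointness rather than the SAM
proper-pair flag: the flag depends on the aligner's insert-size model, while
the fusion definition is gene-centric.  PCR/optical duplicates are dropped
before classification; secondary alignments (0x100) are ignored throughout.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pysam

from .annotation import GenomeAnnotation
from .config import Config

log = logging.getLogger(__name__)

_CIGAR_OPS = "MIDNSHP=X"
# ops that consume reference bases
_REF_OPS = frozenset("MDN=X")
# ops that consume query bases
_QUERY_OPS = frozenset("MIS=X")


class AlignmentInputError(Exception):
    """Unreadable, truncated or otherwise unusable alignment input."""


@dataclass(frozen=True)
class AlignmentSegment:
    """One SAM record, with 1-based inclusive reference coordinates."""

    read_name: str
    chrom: str
    pos: int                       # 1-based leftmost mapped position
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    is_reverse: bool
    is_supplementary: bool
    is_duplicate: bool
    mate_chrom: str | None
    mate_pos: int | None
    read_index: int                # 1 or 2 within the pair

    @property
    def is_primary(self) -> bool:
        return not self.is_supplementary

    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost reference position covered."""
        span = sum(n for op, n in self.cigar if op in _REF_OPS)
        return self.pos + span - 1

    @property
    def left_clip(self) -> int:
        op, n = self.cigar[0]
        return n if op in "SH" else 0

    @property
    def right_clip(self) -> int:
        op, n = self.cigar[-1]
        return n if op in "SH" else 0

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignmentSegment":
        cigar = tuple(
            (_CIGAR_OPS[op], n) for op, n in (rec.cigartuples or ())
        )
        if rec.is_paired:
            read_index = 1 if rec.is_read1 else 2
        else:
            read_index = 1
        return cls(
            read_name=rec.query_name,
            chrom=rec.reference_name,
            pos=rec.reference_start + 1,
            cigar=cigar,
            mapq=rec.mapping_quality,
            is_reverse=rec.is_reverse,
            is_supplementary=rec.is_supplementary,
            is_duplicate=rec.is_duplicate,
            mate_chrom=rec.next_reference_name if rec.is_paired else None,
            mate_pos=rec.next_reference_start + 1 if rec.is_paired else None,
            read_index=read_index,
        )


@dataclass
class DiscordantPair:
    """A read pair whose mates map to disjoint gene sets."""

    read_name: str
    seg1: AlignmentSegment
    seg2: AlignmentSegment
    genes1: frozenset[str]
    genes2: frozenset[str]

    def gene_pairs(self) -> set[frozenset[str]]:
        """All cross-mate unordered gene pairs supported by this pair."""
        return {
            frozenset((a, b)) for a in self.genes1 for b in self.genes2 if a != b
        }


@dataclass
class SplitRead:
    """A single read whose alignment splits across a fusion junction."""

    read_name: str
    read_index: int
    segments: tuple[AlignmentSegment, ...]       # primary first
    genes_per_segment: tuple[frozenset[str], ...]
    junction_pos_1: int    # clip boundary on the primary segment
    junction_pos_2: int    # facing end of the supplementary segment
    primary_clip_side: Literal["left", "right"]

    @property
    def chrom_1(self) -> str:
        return self.segments[0].chrom

    @property
    def chrom_2(self) -> str:
        return self.segments[1].chrom

    @property
    def distinct_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.genes_per_segment:
            out |= gs
        return frozenset(out)

    def gene_pairs(self) -> set[frozenset[str]]:
        g1, g2 = self.genes_per_segment[0], self.genes_per_segment[1]
        return {frozenset((a, b)) for a in g1 for b in g2 if a != b}

    def footprint(self) -> dict[str, list[tuple[int, int]]]:
        """Reference intervals covered by the aligned (non-clipped) segments."""
        out: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for seg in self.segments:
            out[seg.chrom].append((seg.pos, seg.reference_end))
        return dict(out)


def _assign_genes(seg: AlignmentSegment, ann: GenomeAnnotation) -> frozenset[str]:
    return frozenset(
        ann.gene_ids_overlapping(seg.chrom, seg.pos, seg.reference_end)
    )


def classify_pair(
    seg_r1: AlignmentSegment,
    seg_r2: AlignmentSegment,
    ann: GenomeAnnotation,
    cfg: Config,
) -> Literal["discordant", "concordant", "unassigned"]:
    """Gene-centric pair classification.

    Discordant: both mates pass MAPQ, both hit at least one gene, and their
    gene sets are disjoint.  Concordant: the gene sets intersect.  Unassigned:
    either mate hits no gene.
    """
    if seg_r1.read_name != seg_r2.read_name:
        raise ValueError(
            f"segments from different reads: {seg_r1.read_name!r} vs {seg_r2.read_name!r}"
        )
    if seg_r1.mapq < cfg.min_mapq or seg_r2.mapq < cfg.min_mapq:
        return "unassigned"
    g1 = _assign_genes(seg_r1, ann)
    g2 = _assign_genes(seg_r2, ann)
    if not g1 or not g2:
        return "unassigned"
    if g1 & g2:
        return "concordant"
    return "discordant"


def detect_split(
    segments: Iterable[AlignmentSegment],
    ann: GenomeAnnotation,
    cfg: Config,
) -> SplitRead | None:
    """Build a SplitRead from the segments of one physical read, if any.

    Requires a primary alignment carrying a soft-clip of at least
    ``min_clip_len`` together with a supplementary alignment, all segments
    passing MAPQ, and at least two distinct genes across segments.  The
    junction estimate on the primary is the reference coordinate at the clip
    boundary; on the supplementary it is the end facing the clipped sequence.
    """
    segs = [s for s in segments if s.mapq >= cfg.min_mapq]
    primaries = [s for s in segs if s.is_primary]
    supps = [s for s in segs if s.is_supplementary]
    if not primaries or not supps:
        return None
    primary = primaries[0]

    if primary.right_clip >= cfg.min_clip_len and primary.right_clip >= primary.left_clip:
        clip_side: Literal["left", "right"] = "right"
        junction_1 = primary.reference_end
    elif primary.left_clip >= cfg.min_clip_len:
        clip_side = "left"
        junction_1 = primary.pos
    else:
        return None

    # supplementary covering the clipped portion: the facing end is its start
    # when the clip is on the primary's right, its end when on the left
    supp = supps[0]
    junction_2 = supp.pos if clip_side == "right" else supp.reference_end

    used = (primary, supp)
    genes = tuple(_assign_genes(s, ann) for s in used)
    distinct: set[str] = set()
    for gs in genes:
        distinct |= gs
    if len(distinct) < 2:
        return None
    return SplitRead(
        read_name=primary.read_name,
        read_index=primary.read_index,
        segments=used,
        genes_per_segment=genes,
        junction_pos_1=junction_1,
        junction_pos_2=junction_2,
        primary_clip_side=clip_side,
    )


def dedup_evidence(
    pairs: Iterable[DiscordantPair],
    splits: Iterable[SplitRead],
) -> tuple[list[DiscordantPair], list[SplitRead]]:
    """Collapse evidence to at most one support unit per (read name, gene pair).

    One DiscordantPair per read name; one SplitRead per (read name, read
    index, gene-pair set).  A read contributing both a split and a discordant
    signal for the same gene pair is resolved at aggregation time in favour of
    the split tally (direct evidence).
    """
    seen_pairs: set[str] = set()
    out_pairs: list[DiscordantPair] = []
    for p in pairs:
        if p.read_name in seen_pairs:
            continue
        seen_pairs.add(p.read_name)
        out_pairs.append(p)

    seen_splits: set[tuple] = set()
    out_splits: list[SplitRead] = []
    for s in splits:
        key = (s.read_name, s.read_index, frozenset(s.gene_pairs()))
        if key in seen_splits:
            continue
        seen_splits.add(key)
        out_splits.append(s)
    return out_pairs, out_splits


def scan_alignments(
    bam: str | Path,
    ann: GenomeAnnotation,
    cfg: Config,
) -> tuple[list[DiscordantPair], list[SplitRead]]:
    """Stream an alignment file and extract deduplicated fusion evidence.

    Records failing the MAPQ gate, duplicates (unless ``keep_duplicates``)
    and secondary alignments are discarded up front; concordant pairs are
    never emitted.
    """
    by_read: dict[str, dict[int, list[AlignmentSegment]]] = defaultdict(
        lambda: defaultdict(list)
    )
    n_records = n_kept = 0
    try:
        afile = pysam.AlignmentFile(str(bam), check_sq=False)
    except (OSError, ValueError) as exc:
        raise AlignmentInputError(
            f"cannot open alignment file {bam}: {exc}; "
            "input must be a coordinate-sorted SAM/BAM"
        ) from exc
    with afile:
        try:
            for rec in afile.fetch(until_eof=True):
                n_records += 1
                if rec.is_unmapped or rec.is_secondary:
                    continue
                if rec.is_duplicate and not cfg.keep_duplicates:
                    continue
                if rec.mapping_quality < cfg.min_mapq:
                    continue
                seg = AlignmentSegment.from_pysam(rec)
                by_read[seg.read_name][seg.read_index].append(seg)
                n_kept += 1
        except OSError as exc:
            raise AlignmentInputError(f"truncated alignment file {bam}: {exc}") from exc

    pairs: list[DiscordantPair] = []
    splits: list[SplitRead] = []
    for read_name, by_index in by_read.items():
        for idx, segs in by_index.items():
            sr = detect_split(segs, ann, cfg)
            if sr is not None:
                splits.append(sr)
        p1 = next((s for s in by_index.get(1, ()) if s.is_primary), None)
        p2 = next((s for s in by_index.get(2, ()) if s.is_primary), None)
        if p1 is None or p2 is None:
            continue
        if classify_pair(p1, p2, ann, cfg) == "discordant":
            pairs.append(
                DiscordantPair(
                    read_name=read_name,
                    seg1=p1,
                    seg2=p2,
                    genes1=_assign_genes(p1, ann),
                    genes2=_assign_genes(p2, ann),
                )
            )

    pairs, splits = dedup_evidence(pairs, splits)
    log.info(
        "scan_alignments: %d records in, %d passed gates, %d discordant pairs, "
        "%d split reads", n_records, n_kept, len(pairs), len(splits),
    )
    return pairs, splits
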