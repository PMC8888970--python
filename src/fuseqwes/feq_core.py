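"""Fusion equivalence classes and gene-level candidate aggregation.

A discordant read pair whose mates hit the transcript sets {tx_a...} and
{tx_b...} of two different genes is consistent with every cross-gene
transcript combination: the *fusion equivalence class* (FEQ) is exactly that
Cartesian product.  FEQs with identical member sets are merged, pooling their
supporting read names, and evidence is then lifted to the gene level as
fusion-gene candidates carrying deduplicated discordant / split support
counts and breakpoint estimates.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .annotation import GenomeAnnotation
from .read_extraction import AlignmentSegment, DiscordantPair, SplitRead

log = logging.getLogger(__name__)


class EmptyFeqError(Exception):
    """A mate maps inside a gene but overlaps none of its transcripts —
    usually an annotation/alignment build mismatch."""


@dataclass(frozen=True, order=True)
class FusionTranscript:
    """One candidate fused product: a transcript from each partner gene."""

    tx_a: str
    tx_b: str


@dataclass
class FusionEquivalenceClass:
    """The set of fusion transcripts supported by one or more read pairs."""

    members: frozenset[FusionTranscript]
    gene_pair: frozenset[str]
    supporting_read_names: set[str] = field(default_factory=set)
    #: per supporting read: the mate segments, for breakpoint summarization
    support_segments: dict[str, tuple[AlignmentSegment, AlignmentSegment]] = field(
        default_factory=dict
    )


def _mate_transcripts(
    seg: AlignmentSegment, genes: Iterable[str], ann: GenomeAnnotation
) -> set[str]:
    """Transcripts of the assigned genes whose span overlaps the mate."""
    out: set[str] = set()
    for gid in genes:
        for t in ann.transcripts_of(gid):
            if t.chrom == seg.chrom and t.start <= seg.reference_end and t.end >= seg.pos:
                out.add(t.transcript_id)
    return out


def build_feq(pair: DiscordantPair, ann: GenomeAnnotation) -> FusionEquivalenceClass:
    """FEQ of one discordant pair: the cross-gene Cartesian product of the
    two mates' transcript sets (e.g. 2 x 3 transcripts -> 6 fusion transcripts).
    """
    txs1 = _mate_transcripts(pair.seg1, pair.genes1, ann)
    txs2 = _mate_transcripts(pair.seg2, pair.genes2, ann)
    if not txs1 or not txs2:
        raise EmptyFeqError(
            f"read {pair.read_name}: a mate overlaps a gene span but no transcript"
        )
    gene_of = {t: ann.transcripts[t].gene_id for t in txs1 | txs2}
    members = frozenset(
        FusionTranscript(a, b)
        for a in sorted(txs1)
        for b in sorted(txs2)
        if gene_of[a] != gene_of[b]
    )
    gene_pair = frozenset({gene_of[m.tx_a] for m in members}
                          | {gene_of[m.tx_b] for m in members})
    feq = FusionEquivalenceClass(members=members, gene_pair=gene_pair)
    feq.supporting_read_names.add(pair.read_name)
    feq.support_segments[pair.read_name] = (pair.seg1, pair.seg2)
    return feq


def merge_feqs(
    feqs: Iterable[FusionEquivalenceClass],
) -> list[FusionEquivalenceClass]:
    """Merge FEQs with identical member sets, unioning their support."""
    merged: dict[frozenset[FusionTranscript], FusionEquivalenceClass] = {}
    for feq in feqs:
        if feq.members in merged:
            tgt = merged[feq.members]
            tgt.supporting_read_names |= feq.supporting_read_names
            tgt.support_segments.update(feq.support_segments)
        else:
            merged[feq.members] = FusionEquivalenceClass(
                members=feq.members,
                gene_pair=feq.gene_pair,
                supporting_read_names=set(feq.supporting_read_names),
                support_segments=dict(feq.support_segments),
            )
    return sorted(merged.values(), key=lambda f: sorted(f.gene_pair))


@dataclass
class FusionGeneCandidate:
    """Gene-level fusion candidate with deduplicated support counts."""

    gene_a: str
    gene_b: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    n_discordant: int
    n_split: int
    orientation: Literal["a_upstream", "b_upstream", "unknown"] = "unknown"
    filter_flags: set[str] = field(default_factory=set)
    # read names behind each tally, so filters can subtract rejected splits
    discordant_read_names: set[str] = field(default_factory=set)
    split_read_names: set[str] = field(default_factory=set)

    @property
    def n_total(self) -> int:
        return self.n_discordant + self.n_split

    @property
    def gene_pair(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))

    @property
    def passed(self) -> bool:
        return not self.filter_flags


def _median_low(values: list[int]) -> int:
    """Median; for even counts the smaller of the two central values."""
    return int(statistics.median_low(sorted(values)))


def candidates_from_evidence(
    feqs: Iterable[FusionEquivalenceClass],
    splits: Iterable[SplitRead],
    ann: GenomeAnnotation,
) -> list[FusionGeneCandidate]:
    """Aggregate FEQ and split-read evidence into one candidate per gene pair.

    Support is counted in deduplicated read-pair units; a read contributing
    both split and discordant evidence for a gene pair counts once, in the
    split column.  Breakpoints come from the median split junction when split
    evidence exists, otherwise from the innermost discordant mate ends.
    """
    # gene pair -> evidence
    split_names: dict[frozenset[str], set[str]] = {}
    split_junctions: dict[frozenset[str], list[tuple[tuple[str, int], tuple[str, int], str]]] = {}
    disc_names: dict[frozenset[str], set[str]] = {}
    disc_segments: dict[frozenset[str], list[tuple[AlignmentSegment, AlignmentSegment]]] = {}

    splits = list(splits)
    for s in splits:
        for gp in s.gene_pairs():
            split_names.setdefault(gp, set()).add(s.read_name)
            split_junctions.setdefault(gp, []).append(
                ((s.chrom_1, s.junction_pos_1),
                 (s.chrom_2, s.junction_pos_2),
                 s.primary_clip_side)
            )
    for feq in feqs:
        gp = feq.gene_pair
        if len(gp) != 2:
            continue
        disc_names.setdefault(gp, set()).update(feq.supporting_read_names)
        disc_segments.setdefault(gp, []).extend(feq.support_segments.values())

    candidates: list[FusionGeneCandidate] = []
    for gp in sorted(set(split_names) | set(disc_names), key=sorted):
        g_x, g_y = sorted(gp)
        sn = split_names.get(gp, set())
        dn = disc_names.get(gp, set()) - sn  # split outranks discordant per read
        cand = _summarize_candidate(
            g_x, g_y, sn, dn,
            split_junctions.get(gp, []),
            disc_segments.get(gp, []),
            ann,
        )
        candidates.append(cand)
    candidates.sort(key=lambda c: (c.gene_a, c.gene_b))
    return candidates


def _summarize_candidate(
    g_x: str,
    g_y: str,
    split_names: set[str],
    disc_names: set[str],
    junctions: list[tuple[tuple[str, int], tuple[str, int], str]],
    disc_segs: list[tuple[AlignmentSegment, AlignmentSegment]],
    ann: GenomeAnnotation,
) -> FusionGeneCandidate:
    gene_x, gene_y = ann.gene(g_x), ann.gene(g_y)

    upstream_votes: dict[str, int] = {}
    up: str | None = None
    if junctions:
        # group junction coordinates by which gene each side falls in
        bp_x_list: list[int] = []
        bp_y_list: list[int] = []
        for (c1, p1), (c2, p2), clip_side in junctions:
            for chrom, pos in ((c1, p1), (c2, p2)):
                if chrom == gene_x.chrom and gene_x.start <= pos <= gene_x.end:
                    bp_x_list.append(pos)
                elif chrom == gene_y.chrom and gene_y.start <= pos <= gene_y.end:
                    bp_y_list.append(pos)
            # right-end clip on a +strand primary => primary's gene is upstream
            prim_gene = None
            if c1 == gene_x.chrom and gene_x.start <= p1 <= gene_x.end:
                prim_gene = gene_x
            elif c1 == gene_y.chrom and gene_y.start <= p1 <= gene_y.end:
                prim_gene = gene_y
            if prim_gene is not None:
                donates_upstream = (clip_side == "right") == (prim_gene.strand == "+")
                key = prim_gene.gene_id if donates_upstream else (
                    gene_y.gene_id if prim_gene is gene_x else gene_x.gene_id
                )
                upstream_votes[key] = upstream_votes.get(key, 0) + 1
        bp_x = _median_low(bp_x_list) if bp_x_list else gene_x.start
        bp_y = _median_low(bp_y_list) if bp_y_list else gene_y.start
        if upstream_votes:
            up = max(sorted(upstream_votes), key=lambda k: upstream_votes[k])
    else:
        # innermost mate ends: the coordinates facing the junction
        ends_x: list[int] = []
        starts_y: list[int] = []
        for s1, s2 in disc_segs:
            for seg in (s1, s2):
                if seg.chrom == gene_x.chrom and gene_x.start <= seg.pos <= gene_x.end:
                    ends_x.append(seg.reference_end)
                elif seg.chrom == gene_y.chrom and gene_y.start <= seg.pos <= gene_y.end:
                    starts_y.append(seg.pos)
        bp_x = max(ends_x) if ends_x else gene_x.start
        bp_y = min(starts_y) if starts_y else gene_y.start

    # canonicalize by (chrom, pos) of the breakpoints
    if ((gene_x.chrom, bp_x) <= (gene_y.chrom, bp_y)):
        gene_a, bp_a, gene_b, bp_b = gene_x, bp_x, gene_y, bp_y
    else:
        gene_a, bp_a, gene_b, bp_b = gene_y, bp_y, gene_x, bp_x

    if up is None:
        orientation = "unknown"
    else:
        orientation = "a_upstream" if up == gene_a.gene_id else "b_upstream"

    return FusionGeneCandidate(
        gene_a=gene_a.gene_id,
        gene_b=gene_b.gene_id,
        chrom_a=gene_a.chrom,
        pos_a=bp_a,
        chrom_b=gene_b.chrom,
        pos_b=bp_b,
        n_discordant=len(disc_names),
        n_split=len(split_names),
        orientation=orientation,
        discordant_read_names=set(disc_names),
        split_read_names=set(split_names),
    )
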