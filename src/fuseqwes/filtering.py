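"""False-positive filter cascade for fusion-gene candidates.

Candidate-level filters (pure predicates, order-independent):

* ``chromosome`` — both partners on the canonical chromosomes 1-22, X, Y;
* ``biotype``    — both partners protein-coding (``unknown`` fails unless
  ``assume_coding`` is set);
* ``distance``   — same-chromosome partners separated by a nearest-edge gap
  of at least 10 kb (inclusive);
* ``support``    — at least ``min_support`` deduplicated read-pair units;
* ``paralog``    — the gene pair is not flagged by the read-sharing
  simulation;
* ``no_split``   — only when ``require_split`` is set: at least one split
  unit.

Split-level filters run before the support count is final, so a discarded
split read cannot rescue a candidate:

* a split read hitting more than two distinct genes is discarded;
* two overlapping split mates of one pair must leave a non-overlap region
  strictly greater than 20 bases.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .annotation import GenomeAnnotation
from .config import Config, normalize_chrom
from .feq_core import FusionGeneCandidate
from .read_extraction import SplitRead

# re-exported: the configuration type lives conceptually with the thresholds
__all__ = [
    "Config",
    "filter_chromosome", "filter_biotype", "filter_distance", "filter_support",
    "filter_split_gene_count", "filter_split_pair_overlap", "apply_filters",
]

log = logging.getLogger(__name__)


def filter_chromosome(c: FusionGeneCandidate, cfg: Config) -> bool:
    """Pass iff both partner genes sit on whitelisted chromosomes."""
    return (
        normalize_chrom(c.chrom_a) in cfg.allowed_chroms
        and normalize_chrom(c.chrom_b) in cfg.allowed_chroms
    )


def filter_biotype(c: FusionGeneCandidate, ann: GenomeAnnotation, cfg: Config) -> bool:
    """Pass iff both partners are protein-coding (when the filter is on)."""
    if not cfg.require_protein_coding:
        return True
    ok = {"protein_coding"}
    if cfg.assume_coding:
        ok.add("unknown")
    return (
        ann.gene(c.gene_a).biotype in ok and ann.gene(c.gene_b).biotype in ok
    )


def filter_distance(c: FusionGeneCandidate, ann: GenomeAnnotation, cfg: Config) -> bool:
    """Pass iff partners are inter-chromosomal or separated by >= min_gene_distance.

    The gap is nearest-edge: end of the left gene to start of the right gene;
    overlapping or nested genes have gap 0.
    """
    ga, gb = ann.gene(c.gene_a), ann.gene(c.gene_b)
    if ga.chrom != gb.chrom:
        return True
    left, right = (ga, gb) if ga.start <= gb.start else (gb, ga)
    gap = max(0, right.start - left.end - 1)
    return gap >= cfg.min_gene_distance


def filter_support(c: FusionGeneCandidate, cfg: Config) -> bool:
    """Pass iff total deduplicated support reaches the minimum (default 1)."""
    return c.n_total >= cfg.min_support


def filter_split_gene_count(s: SplitRead, cfg: Config) -> bool:
    """Discard split reads mapping to more than two distinct genes."""
    return len(s.distinct_genes) <= cfg.max_genes_per_split


def _interval_union_len(ivs: Sequence[tuple[int, int]]) -> int:
    total = 0
    prev_end = None
    for s, e in sorted(ivs):
        if prev_end is None or s > prev_end:
            total += e - s + 1
            prev_end = e
        elif e > prev_end:
            total += e - prev_end
            prev_end = e
    return total


def filter_split_pair_overlap(s1: SplitRead, s2: SplitRead, cfg: Config) -> bool:
    """For overlapping split mates of one pair, require a non-overlap region
    strictly greater than ``min_split_nonoverlap`` bases.

    Non-overlap is measured on the reference footprints of the two reads'
    aligned segments: |union| - |intersection|.  Mates with no footprint
    overlap are out of the filter's scope and pass.
    """
    if s1.read_name != s2.read_name or s1.read_index == s2.read_index:
        raise ValueError("filter applies to the two mates of one read pair")
    fp1, fp2 = s1.footprint(), s2.footprint()
    inter = 0
    for chrom in set(fp1) & set(fp2):
        for a_s, a_e in fp1[chrom]:
            for b_s, b_e in fp2[chrom]:
                inter += max(0, min(a_e, b_e) - max(a_s, b_s) + 1)
    if inter == 0:
        return True  # not overlapping: rule does not apply
    all_ivs: dict[str, list[tuple[int, int]]] = {}
    for fp in (fp1, fp2):
        for chrom, ivs in fp.items():
            all_ivs.setdefault(chrom, []).extend(ivs)
    union = sum(_interval_union_len(ivs) for ivs in all_ivs.values())
    return (union - inter) > cfg.min_split_nonoverlap


def _apply_split_filters(
    splits: Iterable[SplitRead], cfg: Config
) -> tuple[list[SplitRead], list[SplitRead]]:
    """Run both split-level rules; return (kept, rejected)."""
    splits = list(splits)
    rejected: set[int] = set()
    for i, s in enumerate(splits):
        if not filter_split_gene_count(s, cfg):
            rejected.add(i)
    by_name: dict[str, list[int]] = {}
    for i, s in enumerate(splits):
        by_name.setdefault(s.read_name, []).append(i)
    for name, idxs in by_name.items():
        mates = [i for i in idxs if i not in rejected]
        if len(mates) == 2:
            i, j = mates
            if splits[i].read_index != splits[j].read_index:
                if not filter_split_pair_overlap(splits[i], splits[j], cfg):
                    rejected.update((i, j))
    kept = [s for i, s in enumerate(splits) if i not in rejected]
    rej = [s for i, s in enumerate(splits) if i in rejected]
    return kept, rej


def apply_filters(
    candidates: Iterable[FusionGeneCandidate],
    splits: Iterable[SplitRead],
    ann: GenomeAnnotation,
    paralogs,
    cfg: Config,
) -> tuple[list[FusionGeneCandidate], list[FusionGeneCandidate]]:
    """Apply split-level then candidate-level filters.

    Returns ``(passed, rejected)``; every rejected candidate carries the label
    of each filter it failed in ``filter_flags``.  Support units contributed
    by rejected split reads are subtracted before the support filter runs.
    ``paralogs`` is a :class:`~fuseqwes.paralog_sim.ParalogSet` (or anything
    with a ``contains(gene_a, gene_b)`` method); pass an empty set-like object
    to disable the paralog filter.
    """
    _, rejected_splits = _apply_split_filters(splits, cfg)
    rejected_names: dict[frozenset[str], set[str]] = {}
    for s in rejected_splits:
        for gp in s.gene_pairs():
            rejected_names.setdefault(gp, set()).add(s.read_name)

    passed: list[FusionGeneCandidate] = []
    rejected: list[FusionGeneCandidate] = []
    for c in candidates:
        bad = rejected_names.get(c.gene_pair, set())
        if bad:
            keep = c.split_read_names - bad
            c.n_split = len(keep)
            c.split_read_names = keep
        c.filter_flags = set()
        if not filter_chromosome(c, cfg):
            c.filter_flags.add("chromosome")
        if not filter_biotype(c, ann, cfg):
            c.filter_flags.add("biotype")
        if not filter_distance(c, ann, cfg):
            c.filter_flags.add("distance")
        if not filter_support(c, cfg):
            c.filter_flags.add("support")
        if cfg.require_split and c.n_split == 0:
            c.filter_flags.add("no_split")
        if paralogs is not None and _is_paralog_pair(paralogs, c):
            c.filter_flags.add("paralog")
        (passed if c.passed else rejected).append(c)
    log.info("apply_filters: %d passed, %d rejected", len(passed), len(rejected))
    return passed, rejected


def _is_paralog_pair(paralogs, c: FusionGeneCandidate) -> bool:
    if hasattr(paralogs, "contains"):
        return paralogs.contains(c.gene_a, c.gene_b)
    return c.gene_pair in paralogs
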