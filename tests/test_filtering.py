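"""Filter cascade: each threshold at its boundary, flag completeness,
order independence and monotonicity."""

import itertools

import pytest

from fuseqwes import Config, apply_filters
from fuseqwes.annotation import Exon, Gene, GenomeAnnotation, Transcript
from fuseqwes.feq_core import FusionGeneCandidate
from fuseqwes.filtering import (
    filter_biotype,
    filter_chromosome,
    filter_distance,
    filter_split_gene_count,
    filter_split_pair_overlap,
    filter_support,
)
from fuseqwes.paralog_sim import ParalogSet
from fuseqwes.read_extraction import SplitRead

from conftest import seg


def make_gene(gid, chrom, start, end, biotype="protein_coding"):
    return Gene(gid, gid, chrom, start, end, "+", biotype)


def make_ann(*genes):
    txs = [
        Transcript(f"{g.gene_id}.t1", g.gene_id,
                   [Exon(f"{g.gene_id}.t1", g.chrom, g.start, g.end, 1)])
        for g in genes
    ]
    return GenomeAnnotation(genes, txs)


def make_candidate(ga, gb, n_disc=1, n_split=1):
    names_d = {f"d{i}" for i in range(n_disc)}
    names_s = {f"s{i}" for i in range(n_split)}
    return FusionGeneCandidate(
        gene_a=ga.gene_id, gene_b=gb.gene_id,
        chrom_a=ga.chrom, pos_a=(ga.start + ga.end) // 2,
        chrom_b=gb.chrom, pos_b=(gb.start + gb.end) // 2,
        n_discordant=n_disc, n_split=n_split,
        discordant_read_names=names_d, split_read_names=names_s,
    )


CFG = Config()


@pytest.mark.parametrize("chrom_a,chrom_b,expected", [
    ("chr15", "chr17", True),     # classic t(15;17) geometry
    ("15", "X", True),            # prefixless dialect, sex chromosome
    ("chrM", "chr1", False),      # mitochondrial excluded
    ("GL000220.1", "chr1", False),  # unplaced scaffold excluded
])
def test_filter_chromosome(chrom_a, chrom_b, expected):
    ga = make_gene("a", chrom_a, 100, 200)
    gb = make_gene("b", chrom_b, 100, 200)
    assert filter_chromosome(make_candidate(ga, gb), CFG) is expected


@pytest.mark.parametrize("bt_a,bt_b,assume,expected", [
    ("protein_coding", "protein_coding", False, True),
    ("protein_coding", "lincRNA", False, False),
    ("protein_coding", "unknown", False, False),  # conservative default
    ("protein_coding", "unknown", True, True),    # --assume-coding override
])
def test_filter_biotype(bt_a, bt_b, assume, expected):
    ga = make_gene("a", "chr1", 100, 200, bt_a)
    gb = make_gene("b", "chr2", 100, 200, bt_b)
    ann = make_ann(ga, gb)
    cfg = CFG.replace(assume_coding=assume)
    assert filter_biotype(make_candidate(ga, gb), ann, cfg) is expected


@pytest.mark.parametrize("gap,expected", [
    (9_999, False),   # just under the 10 kb threshold
    (10_000, True),   # inclusive boundary
    (50_000, True),
])
def test_filter_distance_same_chromosome(gap, expected):
    ga = make_gene("a", "chr1", 1_000, 2_000)
    gb = make_gene("b", "chr1", 2_000 + gap + 1, 2_000 + gap + 1_000)
    ann = make_ann(ga, gb)
    assert filter_distance(make_candidate(ga, gb), ann, CFG) is expected


def test_filter_distance_interchromosomal_always_passes():
    ga = make_gene("a", "chr1", 1_000, 2_000)
    gb = make_gene("b", "chr2", 2_100, 3_000)
    ann = make_ann(ga, gb)
    assert filter_distance(make_candidate(ga, gb), ann, CFG) is True


@pytest.mark.parametrize("n_total,min_support,expected", [
    (1, 1, True),    # the stated minimum of one read pair
    (0, 1, False),
    (2, 3, False),   # raised threshold
])
def test_filter_support(n_total, min_support, expected):
    ga = make_gene("a", "chr1", 100, 200)
    gb = make_gene("b", "chr2", 100, 200)
    c = make_candidate(ga, gb, n_disc=n_total, n_split=0)
    assert filter_support(c, CFG.replace(min_support=min_support)) is expected


def _split(name, read_index, segments, genes):
    return SplitRead(
        read_name=name, read_index=read_index, segments=tuple(segments),
        genes_per_segment=tuple(frozenset(g) for g in genes),
        junction_pos_1=segments[0].reference_end,
        junction_pos_2=segments[1].pos,
        primary_clip_side="right",
    )


@pytest.mark.parametrize("genes,expected", [
    ((("G1",), ("G2",)), True),           # 2 distinct genes
    ((("G1", "G3"), ("G2",)), False),     # 3 distinct genes
    ((("G1",), ("G1",)), True),           # 1 gene passes the count rule
])
def test_filter_split_gene_count(genes, expected):
    segs = [seg("s", "chr1", 1000, "60M40S"),
            seg("s", "chr2", 2000, "60S40M", supplementary=True)]
    assert filter_split_gene_count(_split("s", 1, segs, genes), CFG) is expected


@pytest.mark.parametrize("m_len,start,expected", [
    (39, 1021, True),    # non-overlap 21 bp: strictly over 20 -> pass
    (40, 1020, False),   # non-overlap 20 bp: fail under the strict reading
])
def test_filter_split_pair_overlap_boundary(m_len, start, expected):
    # mate 2's chr1 footprint is nested at the end of mate 1's 60 bp match and
    # the chr2 footprints coincide, so |union| - |intersection| == 60 - m_len
    s1segs = [seg("r", "chr1", 1000, "60M40S", read_index=1),
              seg("r", "chr2", 5000, "60S40M", read_index=1, supplementary=True)]
    s2segs = [seg("r", "chr1", start, f"{m_len}M{100 - m_len}S", read_index=2,
                  reverse=True),
              seg("r", "chr2", 5000, "60S40M",
                  read_index=2, supplementary=True, reverse=True)]
    s1 = _split("r", 1, s1segs, (("G1",), ("G2",)))
    s2 = _split("r", 2, s2segs, (("G1",), ("G2",)))
    assert filter_split_pair_overlap(s1, s2, CFG) is expected


def test_filter_split_pair_overlap_disjoint_mates_pass():
    s1segs = [seg("r", "chr1", 1000, "60M40S", read_index=1),
              seg("r", "chr2", 5000, "60S40M", read_index=1, supplementary=True)]
    s2segs = [seg("r", "chr1", 9000, "60M40S", read_index=2),
              seg("r", "chr2", 9000, "60S40M", read_index=2, supplementary=True)]
    s1 = _split("r", 1, s1segs, (("G1",), ("G2",)))
    s2 = _split("r", 2, s2segs, (("G1",), ("G2",)))
    assert filter_split_pair_overlap(s1, s2, CFG) is True


# --- apply_filters -----------------------------------------------------------

def _six_candidate_fixture():
    """6 candidates: 2 fail distance, 1 fails biotype, 3 pass (manual oracle)."""
    genes = {
        "A": make_gene("A", "chr1", 10_000, 12_000),
        "B": make_gene("B", "chr1", 17_000, 19_000),        # gap 4,999 to A
        "C": make_gene("C", "chr1", 40_000, 42_000),        # far from all chr1
        "D": make_gene("D", "chr1", 50_001, 52_000),        # gap 8,000 to C: fail
        "E": make_gene("E", "chr2", 10_000, 12_000, "lincRNA"),
        "F": make_gene("F", "chr2", 40_000, 42_000),
        "H": make_gene("H", "chr3", 10_000, 12_000),
    }
    ann = make_ann(*genes.values())
    cands = [
        make_candidate(genes["A"], genes["B"]),   # distance fail (gap 4,999)
        make_candidate(genes["C"], genes["D"]),   # distance fail (gap 7,999)
        make_candidate(genes["E"], genes["F"]),   # biotype fail (lincRNA)
        make_candidate(genes["A"], genes["C"]),   # pass (gap 27,999)
        make_candidate(genes["A"], genes["F"]),   # pass (inter-chromosomal)
        make_candidate(genes["F"], genes["H"]),   # pass (inter-chromosomal)
    ]
    return ann, cands


def test_apply_filters_manual_oracle():
    ann, cands = _six_candidate_fixture()
    passed, rejected = apply_filters(cands, [], ann, ParalogSet(), CFG)
    assert len(passed) == 3
    flags = {(c.gene_a, c.gene_b): c.filter_flags for c in rejected}
    assert flags[("A", "B")] == {"distance"}
    assert flags[("C", "D")] == {"distance"}
    assert flags[("E", "F")] == {"biotype"}
    # completeness: every rejected candidate fails at least one named filter
    assert all(c.filter_flags for c in rejected)


def test_apply_filters_idempotent():
    ann, cands = _six_candidate_fixture()
    passed, _ = apply_filters(cands, [], ann, ParalogSet(), CFG)
    passed2, rejected2 = apply_filters(passed, [], ann, ParalogSet(), CFG)
    assert rejected2 == []
    assert [(c.gene_a, c.gene_b) for c in passed2] == \
           [(c.gene_a, c.gene_b) for c in passed]


def test_candidate_filters_order_independent():
    """Pure predicates: the pass set is the same under any evaluation order."""
    ann, cands = _six_candidate_fixture()
    preds = [
        lambda c: filter_chromosome(c, CFG),
        lambda c: filter_biotype(c, ann, CFG),
        lambda c: filter_distance(c, ann, CFG),
        lambda c: filter_support(c, CFG),
    ]
    reference = None
    for order in itertools.permutations(range(4)):
        passing = {
            (c.gene_a, c.gene_b) for c in cands if all(preds[i](c) for i in order)
        }
        if reference is None:
            reference = passing
        assert passing == reference


def test_monotonicity_in_thresholds():
    ann, cands = _six_candidate_fixture()

    def pass_set(cfg):
        passed, _ = apply_filters(
            [make_candidate(ann.gene(c.gene_a), ann.gene(c.gene_b),
                            c.n_discordant, c.n_split) for c in cands],
            [], ann, ParalogSet(), cfg)
        return {(c.gene_a, c.gene_b) for c in passed}

    base = pass_set(CFG)
    assert pass_set(CFG.replace(min_support=5)) <= base
    assert pass_set(CFG.replace(allowed_chroms=frozenset({"1", "2"}))) <= base


def test_rejected_split_cannot_rescue_support(ann):
    """A split read failing the gene-count rule is subtracted before the
    support filter, so a candidate with only that evidence is rejected."""
    g1, g2 = ann.gene("G1"), ann.gene("G2")
    segs = [seg("s", g1.chrom, g1.start + 100, "60M40S"),
            seg("s", g2.chrom, g2.start + 100, "60S40M", supplementary=True)]
    bad_split = _split("s", 1, segs, (("G1", "G3"), ("G2",)))  # 3 genes
    cand = FusionGeneCandidate(
        gene_a="G1", gene_b="G2", chrom_a=g1.chrom, pos_a=g1.start + 159,
        chrom_b=g2.chrom, pos_b=g2.start + 100,
        n_discordant=0, n_split=1,
        split_read_names={"s"},
    )
    passed, rejected = apply_filters([cand], [bad_split], ann, ParalogSet(), CFG)
    assert passed == []
    assert rejected[0].filter_flags >= {"support"}
    assert rejected[0].n_split == 0


def test_paralog_flag(ann):
    g1, g2 = ann.gene("G1"), ann.gene("G2")
    cand = make_candidate(g1, g2)
    ps = ParalogSet()
    ps.add("G1", "G2")
    passed, rejected = apply_filters([cand], [], ann, ps, CFG)
    assert passed == [] and rejected[0].filter_flags == {"paralog"}
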