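"""Shared fixtures: toy references, planted-fusion alignments, and helpers
for hand-building alignment segments and small SAM files."""

from __future__ import annotations

import re
from pathlib import Path

import pysam
import pytest

from fuseqwes import (
    Config,
    FusionSpec,
    make_toy_reference,
    plant_fusion_reads,
)
from fuseqwes.read_extraction import AlignmentSegment

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(s: str) -> tuple[tuple[str, int], ...]:
    return tuple((op, int(n)) for n, op in _CIG_RE.findall(s))


def seg(
    name: str = "r1",
    chrom: str = "chr1",
    pos: int = 1000,
    cigar: str = "100M",
    mapq: int = 60,
    read_index: int = 1,
    supplementary: bool = False,
    duplicate: bool = False,
    reverse: bool = False,
    mate_chrom: str | None = None,
    mate_pos: int | None = None,
) -> AlignmentSegment:
    """Terse constructor for hand-built alignment segments."""
    return AlignmentSegment(
        read_name=name, chrom=chrom, pos=pos, cigar=parse_cigar(cigar),
        mapq=mapq, is_reverse=reverse, is_supplementary=supplementary,
        is_duplicate=duplicate, mate_chrom=mate_chrom, mate_pos=mate_pos,
        read_index=read_index,
    )


def write_sam(records: list[dict], chrom_lens: dict[str, int], path: Path) -> Path:
    """Write hand-specified records (dicts of SAM fields) to a SAM file."""
    chroms = sorted(chrom_lens)
    tid = {c: i for i, c in enumerate(chroms)}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_lens[c]} for c in chroms],
    }
    records = sorted(records, key=lambda r: (tid[r["chrom"]], r["pos"]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["qname"]
            a.flag = r["flag"]
            a.reference_id = tid[r["chrom"]]
            a.reference_start = r["pos"] - 1
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = r["cigar"]
            a.next_reference_id = tid[r.get("rnext", r["chrom"])]
            a.next_reference_start = r.get("pnext", r["pos"]) - 1
            qlen = sum(n for n, op in
                       ((int(m.group(1)), m.group(2)) for m in _CIG_RE.finditer(r["cigar"]))
                       if op in "MIS=X")
            a.query_sequence = r.get("seq", "A" * qlen)
            if "sa" in r:
                a.set_tag("SA", r["sa"])
            out.write(a)
    return path


@pytest.fixture(scope="session")
def toy_ref():
    """4 genes x 2 transcripts on 2 chromosomes, deterministic."""
    return make_toy_reference(seed=7)


@pytest.fixture(scope="session")
def ann(toy_ref):
    return toy_ref.annotation


@pytest.fixture(scope="session")
def cfg():
    return Config()


@pytest.fixture(scope="session")
def fusion_spec(ann):
    ga, gb = ann.gene("G1"), ann.gene("G2")
    return FusionSpec(
        gene_a="G1", gene_b="G2",
        break_a=(ga.start + ga.end) // 2,
        break_b=(gb.start + gb.end) // 2,
        fraction=0.5,
    )


@pytest.fixture(scope="session")
def planted(toy_ref, fusion_spec, tmp_path_factory):
    """150x planted inter-chromosomal fusion: (sam path, ground truth)."""
    d = tmp_path_factory.mktemp("planted")
    sam = d / "planted.sam"
    truth = plant_fusion_reads(
        toy_ref, fusion_spec, coverage=150, seed=11, out_sam=sam
    )
    return sam, truth
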