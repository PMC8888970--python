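"""Synthetic ground-truth data: toy references, planted-fusion alignments,
pair-atomic subsampling and a coverage-sensitivity harness.

The generator emulates targeted-panel / exome DNA sequencing around a planted
fusion: paired-end reads (default 100 bp, insert ~N(350, 50) truncated) drawn
from a fused allele at a configurable tumor fraction and from the wild-type
alleles otherwise.  Reads crossing the breakpoint are emitted exactly as a
chimeric aligner would report them — a soft-clipped primary record plus a
supplementary record with reciprocal SA tags — while junction-spanning pairs
become mates on the two partner genes.  Every read is labeled
(fusion-split / fusion-spanning-pair / background) so recovery is checkable
against ground truth.

Subsampling is per read *pair* (all records of a read name kept or dropped
atomically) via a salted hash of the read name, which makes subsamples at
decreasing fractions nested under one seed — mirroring coverage-titration
designs that subsample 1500x panel data down to 7.5x.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import Exon, Gene, GenomeAnnotation, Transcript, write_gtf
from .config import Config
from .paralog_sim import TranscriptSequence

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# toy reference
# ---------------------------------------------------------------------------

@dataclass
class ToyReference:
    """In-memory synthetic genome + annotation + spliced transcripts."""

    genome: dict[str, str]
    annotation: GenomeAnnotation

    def transcript_sequences(self) -> list[TranscriptSequence]:
        out = []
        for t in self.annotation.transcripts.values():
            seq = "".join(
                self.genome[e.chrom][e.start - 1:e.end] for e in t.exons
            )
            out.append(TranscriptSequence(t.transcript_id, seq))
        return out

    def write_genome_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        write_gtf(self.annotation, path)

    def write_tx_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ts in sorted(self.transcript_sequences(), key=lambda t: t.transcript_id):
                fh.write(f">{ts.transcript_id}\n{ts.sequence}\n")


def make_toy_reference(
    n_genes: int = 4,
    gene_len: int = 3000,
    n_tx_per_gene: int = 2,
    seed: int = 0,
    n_chroms: int = 2,
    intergenic: int = 20_000,
    exons_per_gene: int = 3,
    duplicate_pair: bool = False,
    noncoding: Sequence[int] = (),
    chrom_names: Sequence[str] | None = None,
) -> ToyReference:
    """Random multi-exon toy genome, deterministic under ``seed``.

    Genes (ids ``G1..Gn``) are laid out round-robin across chromosomes with
    ``intergenic`` bp between them, each with ``exons_per_gene`` exons and
    ``n_tx_per_gene`` transcripts (the full exon chain plus chains dropping
    interior exons).  ``duplicate_pair=True`` copies G1's genomic sequence
    onto G2, producing an exact sequence paralog; indices in ``noncoding``
    (1-based gene numbers) get biotype ``lincRNA`` instead of protein_coding.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if intergenic < 0 or gene_len <= 0:
        raise ValueError("layout parameters imply overlapping genes")
    if exons_per_gene < 1 or n_tx_per_gene < 1:
        raise ValueError("need >=1 exon and >=1 transcript per gene")
    if n_tx_per_gene > 1 and exons_per_gene < 3:
        raise ValueError("multiple transcripts require >=3 exons to differ")

    rng = np.random.default_rng(seed)
    if chrom_names is None:
        chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    else:
        n_chroms = len(chrom_names)

    per_chrom = [len(range(i, n_genes, n_chroms)) for i in range(n_chroms)]
    chrom_len = {
        chrom_names[i]: intergenic + per_chrom[i] * (gene_len + intergenic)
        for i in range(n_chroms)
    }
    genome = {
        c: "".join(rng.choice(list("ACGT"), size=L))
        for c, L in sorted(chrom_len.items())
    }

    # exon layout inside a gene: alternating exon/intron blocks
    n_blocks = 2 * exons_per_gene - 1
    block = gene_len // n_blocks
    exon_offsets = [
        (k * 2 * block, k * 2 * block + block - 1) for k in range(exons_per_gene)
    ]
    # stretch the last exon to the gene end
    exon_offsets[-1] = (exon_offsets[-1][0], gene_len - 1)

    genes: list[Gene] = []
    transcripts: list[Transcript] = []
    cursor = {c: intergenic + 1 for c in chrom_names}
    for i in range(n_genes):
        chrom = chrom_names[i % n_chroms]
        start = cursor[chrom]
        end = start + gene_len - 1
        cursor[chrom] = end + intergenic + 1
        gid = f"G{i + 1}"
        biotype = "lincRNA" if (i + 1) in set(noncoding) else "protein_coding"
        genes.append(Gene(gid, f"GENE{i + 1}", chrom, start, end, "+", biotype))
        exon_coords = [(start + s, start + e) for s, e in exon_offsets]
        for j in range(n_tx_per_gene):
            tid = f"{gid}.t{j + 1}"
            if j == 0 or exons_per_gene < 3:
                chosen = list(range(exons_per_gene))
            else:
                # drop one interior exon per extra transcript
                drop = 1 + (j - 1) % (exons_per_gene - 2)
                chosen = [k for k in range(exons_per_gene) if k != drop]
            exons = [
                Exon(tid, chrom, exon_coords[k][0], exon_coords[k][1], n + 1)
                for n, k in enumerate(chosen)
            ]
            transcripts.append(Transcript(tid, gid, exons))

    if duplicate_pair:
        g1, g2 = genes[0], genes[1]
        src = genome[g1.chrom][g1.start - 1:g1.end]
        tgt = genome[g2.chrom]
        genome[g2.chrom] = tgt[:g2.start - 1] + src + tgt[g2.end:]

    return ToyReference(genome=genome, annotation=GenomeAnnotation(genes, transcripts))


# ---------------------------------------------------------------------------
# planted fusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionSpec:
    """A planted fusion: gene A up to break_a joined to gene B from break_b."""

    gene_a: str
    gene_b: str
    break_a: int
    break_b: int
    fraction: float = 0.5       # tumor fraction of pairs from the fused allele
    orientation: str = "a_upstream"

    def validate(self, ann: GenomeAnnotation) -> None:
        ga, gb = ann.gene(self.gene_a), ann.gene(self.gene_b)
        if not ga.start <= self.break_a <= ga.end:
            raise ValueError(f"break_a {self.break_a} outside {self.gene_a} span")
        if not gb.start <= self.break_b <= gb.end:
            raise ValueError(f"break_b {self.break_b} outside {self.gene_b} span")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.orientation != "a_upstream":
            raise ValueError("only a_upstream fusion geometry is generated")


@dataclass
class GroundTruth:
    """Per-read-pair labels recorded while generating planted reads."""

    spec: FusionSpec
    labels: dict[str, str] = field(default_factory=dict)
    #: junction-crossing reads with >= min_clip aligned on both sides:
    #: the pipeline-recoverable split-read upper bound
    recoverable_split_reads: int = 0

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_name\tlabel\n")
            for name in sorted(self.labels):
                fh.write(f"{name}\t{self.labels[name]}\n")


def _truncated_normal_insert(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    for _ in range(100):
        v = int(round(rng.normal(mean, sd)))
        if lo <= v <= hi:
            return v
    return int(min(max(lo, mean), hi))


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < error_rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def plant_fusion_reads(
    ref: ToyReference,
    spec: FusionSpec,
    coverage: float,
    read_len: int = 100,
    insert_mean: int = 350,
    insert_sd: int = 50,
    seed: int = 0,
    out_sam: str | Path = "planted.sam",
    pad: int = 500,
    error_rate: float = 0.0,
    min_clip: int = 20,
) -> GroundTruth:
    """Simulate paired-end reads over a planted fusion and write sorted SAM.

    Coverage is the mean fold-coverage over the padded fusion region; a
    ``spec.fraction`` share of pairs comes from the fused allele, the rest
    from the wild-type alleles of both partners.  Junction-crossing reads are
    written as soft-clipped primary + supplementary records with reciprocal
    SA tags; all MAPQ are 60.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    spec.validate(ref.annotation)
    rng = np.random.default_rng(seed)
    ann = ref.annotation
    ga, gb = ann.gene(spec.gene_a), ann.gene(spec.gene_b)

    ra_start = max(1, ga.start - pad)
    ra_end = min(len(ref.genome[ga.chrom]), ga.end + pad)
    rb_start = max(1, gb.start - pad)
    rb_end = min(len(ref.genome[gb.chrom]), gb.end + pad)

    # fused contig: A[ra_start..break_a] + B[break_b..rb_end]
    part_a = ref.genome[ga.chrom][ra_start - 1:spec.break_a]
    part_b = ref.genome[gb.chrom][spec.break_b - 1:rb_end]
    fused = part_a + part_b
    junction_offset = len(part_a)        # last A base, 1-based on the contig

    records: list[dict] = []
    truth = GroundTruth(spec=spec)
    serial = 0

    def frag_positions(L: int, n_pairs: int) -> list[tuple[int, int]]:
        out = []
        lo = 2 * read_len
        hi = min(L, int(insert_mean + 4 * insert_sd))
        if L < lo:
            return out
        for _ in range(n_pairs):
            isize = _truncated_normal_insert(rng, insert_mean, insert_sd, lo, hi)
            start = int(rng.integers(1, L - isize + 2))   # 1-based
            out.append((start, start + isize - 1))
        return out

    def map_back(u: int, v: int) -> list[dict]:
        """Map 1-based contig interval [u, v] to reference alignment parts."""
        if v <= junction_offset:
            return [dict(chrom=ga.chrom, pos=ra_start + u - 1,
                         cigar=f"{read_len}M", clip=None)]
        if u > junction_offset:
            return [dict(chrom=gb.chrom, pos=spec.break_b + (u - junction_offset) - 1,
                         cigar=f"{read_len}M", clip=None)]
        L1 = junction_offset - u + 1
        L2 = v - junction_offset
        rec_a = dict(chrom=ga.chrom, pos=ra_start + u - 1,
                     cigar=f"{L1}M{L2}S", clip=("right", L1, L2))
        rec_b = dict(chrom=gb.chrom, pos=spec.break_b,
                     cigar=f"{L1}S{L2}M", clip=("left", L1, L2))
        # larger aligned part is the primary
        return [rec_a, rec_b] if L1 >= L2 else [rec_b, rec_a]

    def emit_pair(name: str, seq1: str, parts1: list[dict], seq2: str,
                  parts2: list[dict], proper: bool) -> None:
        m1, m2 = parts1[0], parts2[0]
        for idx, (seq, parts, mate) in enumerate(
            ((seq1, parts1, m2), (seq2, parts2, m1)), start=1
        ):
            is_reverse = idx == 2
            mate_reverse = idx == 1
            strand = "-" if is_reverse else "+"
            for k, part in enumerate(parts):
                flag = 0x1 | (0x40 if idx == 1 else 0x80)
                if proper:
                    flag |= 0x2
                if is_reverse:
                    flag |= 0x10
                if mate_reverse:
                    flag |= 0x20
                if k > 0:
                    flag |= 0x800
                sa = None
                if len(parts) > 1:
                    other = parts[1 - k]
                    sa = (f"{other['chrom']},{other['pos']},{strand},"
                          f"{other['cigar']},60,0;")
                records.append(dict(
                    qname=name, flag=flag, chrom=part["chrom"], pos=part["pos"],
                    mapq=60, cigar=part["cigar"], rnext=mate["chrom"],
                    pnext=mate["pos"], seq=seq, sa=sa,
                ))

    # pair budget: coverage is mean depth over the simulated footprint, and
    # spec.fraction of all pairs comes from the fused allele
    len_a = ra_end - ra_start + 1
    len_b = rb_end - rb_start + 1
    n_total_pairs = int(round(coverage * (len_a + len_b) / (2 * read_len)))
    n_fusion_pairs = int(round(spec.fraction * n_total_pairs))
    for s, e in frag_positions(len(fused), n_fusion_pairs):
        serial += 1
        name = f"fx{serial:07d}"
        u1, v1 = s, s + read_len - 1
        u2, v2 = e - read_len + 1, e
        seq1 = _mutate(fused[u1 - 1:v1], rng, error_rate)
        seq2 = _mutate(fused[u2 - 1:v2], rng, error_rate)
        parts1, parts2 = map_back(u1, v1), map_back(u2, v2)
        crosses1 = len(parts1) > 1
        crosses2 = len(parts2) > 1
        if crosses1 or crosses2:
            truth.labels[name] = "fusion-split"
            for parts in (parts1, parts2):
                if len(parts) > 1:
                    _, L1, L2 = parts[0]["clip"]
                    if min(L1, L2) >= min_clip:
                        truth.recoverable_split_reads += 1
        elif (v1 <= junction_offset) != (v2 <= junction_offset):
            truth.labels[name] = "fusion-spanning-pair"
        else:
            truth.labels[name] = "background"
        emit_pair(name, seq1, parts1, seq2, parts2, proper=False)

    # --- wild-type pairs, split between the two regions by length -----------
    n_wt_pairs = n_total_pairs - n_fusion_pairs
    for chrom, lo, hi, tag, share in (
        (ga.chrom, ra_start, ra_end, "wa", len_a / (len_a + len_b)),
        (gb.chrom, rb_start, rb_end, "wb", len_b / (len_a + len_b)),
    ):
        L = hi - lo + 1
        n_pairs = int(round(n_wt_pairs * share))
        seq_region = ref.genome[chrom][lo - 1:hi]
        for s, e in frag_positions(L, n_pairs):
            serial += 1
            name = f"{tag}{serial:07d}"
            truth.labels[name] = "background"
            seq1 = _mutate(seq_region[s - 1:s + read_len - 1], rng, error_rate)
            seq2 = _mutate(seq_region[e - read_len:e], rng, error_rate)
            p1 = [dict(chrom=chrom, pos=lo + s - 1, cigar=f"{read_len}M", clip=None)]
            p2 = [dict(chrom=chrom, pos=lo + e - read_len, cigar=f"{read_len}M", clip=None)]
            emit_pair(name, seq1, p1, seq2, p2, proper=True)

    _write_sam(records, ref, out_sam)
    log.info(
        "plant_fusion_reads: %d pairs (%d fusion-split, %d spanning), %d records -> %s",
        len(truth.labels), truth.count("fusion-split"),
        truth.count("fusion-spanning-pair"), len(records), out_sam,
    )
    return truth


def _write_sam(records: list[dict], ref: ToyReference, path: str | Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(ref.genome[c])} for c in sorted(ref.genome)],
    }
    tid = {c: i for i, c in enumerate(sorted(ref.genome))}
    records = sorted(records, key=lambda r: (tid[r["chrom"]], r["pos"], r["qname"]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["qname"]
            a.flag = r["flag"]
            a.reference_id = tid[r["chrom"]]
            a.reference_start = r["pos"] - 1
            a.mapping_quality = r["mapq"]
            a.cigarstring = r["cigar"]
            a.next_reference_id = tid[r["rnext"]]
            a.next_reference_start = r["pnext"] - 1
            a.template_length = 0
            a.query_sequence = r["seq"]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
            if r["sa"]:
                a.set_tag("SA", r["sa"])
            out.write(a)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def _keep_fraction(read_name: str, seed: int) -> float:
    """Stable uniform deviate in [0, 1) for a (read name, seed) pair."""
    digest = hashlib.md5(f"{seed}:{read_name}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def subsample_alignments(
    bam: str | Path,
    fraction: float,
    seed: int,
    out: str | Path,
) -> int:
    """Keep each read pair (all records of a read name) with probability
    ``fraction``; returns the number of read names kept.

    The decision is a salted hash of the read name, so for a fixed seed the
    kept set at a smaller fraction is a subset of the kept set at a larger
    one (nested subsamples).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    kept_names: set[str] = set()
    with pysam.AlignmentFile(str(bam), check_sq=False) as fin:
        with pysam.AlignmentFile(str(out), "w", template=fin) as fout:
            for rec in fin.fetch(until_eof=True):
                if _keep_fraction(rec.query_name, seed) < fraction:
                    kept_names.add(rec.query_name)
                    fout.write(rec)
    return len(kept_names)


# ---------------------------------------------------------------------------
# sensitivity harness
# ---------------------------------------------------------------------------

def sensitivity_curve(
    ref: ToyReference,
    spec: FusionSpec,
    fractions: Sequence[float],
    n_replicates: int,
    cfg: Config,
    seed: int,
    base_coverage: float = 1500.0,
    workdir: str | Path | None = None,
    read_len: int = 100,
) -> pd.DataFrame:
    """Run the full pipeline on nested subsamples of planted-fusion data.

    For each replicate a fresh alignment set is generated at
    ``base_coverage``; each fraction is then drawn with the replicate's
    subsampling seed (shared across fractions, so subsamples are nested) and
    the pipeline's detection of the planted gene pair and its support counts
    are recorded.
    """
    from .pipeline import run_pipeline  # local import: avoids a cycle

    import tempfile

    if workdir is None:
        tmp = tempfile.TemporaryDirectory()
        workdir = Path(tmp.name)
    else:
        tmp = None
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)

    target = frozenset((spec.gene_a, spec.gene_b))
    rows = []
    try:
        for rep in range(n_replicates):
            gen_seed = (seed + 7919 * (rep + 1)) % (2**31)
            full = workdir / f"rep{rep}.sam"
            plant_fusion_reads(
                ref, spec, coverage=base_coverage, read_len=read_len,
                seed=gen_seed, out_sam=full,
            )
            sub_seed = (seed + 104729 * (rep + 1)) % (2**31)
            for frac in fractions:
                sub = workdir / f"rep{rep}_f{frac}.sam"
                subsample_alignments(full, frac, sub_seed, sub)
                table = run_pipeline(sub, ref.annotation, cfg)
                hit = next(
                    (c for c in table.rows if c.gene_pair == target), None
                )
                rows.append(dict(
                    replicate=rep,
                    fraction=frac,
                    coverage=base_coverage * frac,
                    detected=hit is not None,
                    n_support=hit.n_total if hit else 0,
                    n_split=hit.n_split if hit else 0,
                    n_discordant=hit.n_discordant if hit else 0,
                ))
                sub.unlink()
            full.unlink()
    finally:
        if tmp is not None:
            tmp.cleanup()
    return pd.DataFrame(rows)
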