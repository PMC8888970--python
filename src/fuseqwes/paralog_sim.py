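"""Simulation-based paralog detection.

Paralogous genes with near-identical sequence are a primary source of false
fusion calls: reads from one paralog multi-map to the other and mimic
cross-gene evidence.  To flag such pairs we simulate a large number of
error-free reads (default 10,000) uniformly from every spliced transcript,
re-map them by exact substring matching, and summarize the read sharing
between transcripts — a direct indicator of sequence similarity.  Sharing is
lifted from transcript to gene level: a gene pair is paralogous as soon as
any cross-gene transcript pair shares at least ``share_frac`` of either
side's reads.  Candidate fusions between paralogous genes are discarded.

The exact-substring mapper replaces an external aligner; a different mapper
can be injected through the ``mapper`` hook of :func:`map_simulated`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from pyfaidx import Fasta

from .annotation import GenomeAnnotation
from .feq_core import FusionGeneCandidate

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptSequence:
    """A spliced transcript sequence used for read simulation."""

    transcript_id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{self.transcript_id}: non-nucleotide characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class SimulatedRead:
    origin_tx: str
    start: int        # 0-based start within the origin transcript
    sequence: str


@dataclass
class SharingMatrix:
    """Sparse (origin, target) -> shared-read counts from the simulation."""

    counts: dict[tuple[str, str], int]
    reads_per_tx: int
    transcripts: tuple[str, ...]

    def fraction(self, tx_i: str, tx_j: str) -> float:
        denom = self.counts.get((tx_i, tx_i), 0)
        if denom == 0:
            return 0.0
        return self.counts.get((tx_i, tx_j), 0) / denom


@dataclass
class ParalogSet:
    """Unordered gene pairs flagged as sequence-paralogous."""

    pairs: set[frozenset[str]] = field(default_factory=set)

    def contains(self, gene_a: str, gene_b: str) -> bool:
        return frozenset((gene_a, gene_b)) in self.pairs

    def add(self, gene_a: str, gene_b: str) -> None:
        if gene_a == gene_b:
            raise ValueError("paralog pairs are between distinct genes")
        self.pairs.add(frozenset((gene_a, gene_b)))

    def __len__(self) -> int:
        return len(self.pairs)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for pair in sorted(self.pairs, key=sorted):
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ParalogSet":
        out = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("gene_a"):
                # headerless two-column file
                a, b = header.split()[:2]
                out.add(a, b)
            for line in fh:
                if line.strip():
                    a, b = line.split()[:2]
                    out.add(a, b)
        return out


def load_transcript_fasta(path: str | Path) -> list[TranscriptSequence]:
    """Read spliced transcript sequences from a FASTA file."""
    fa = Fasta(str(path))
    return [TranscriptSequence(name, str(fa[name][:]).upper()) for name in fa.keys()]


def simulate_reads(
    txs: Iterable[TranscriptSequence],
    n_per_tx: int,
    read_len: int = 100,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Uniform error-free single-end reads from every eligible transcript.

    Each transcript at least ``read_len`` long yields exactly ``n_per_tx``
    reads with uniformly random start positions; shorter transcripts are
    skipped with a warning.  Deterministic under ``seed``.
    """
    if n_per_tx < 1:
        raise ValueError("n_per_tx must be >= 1")
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for tx in sorted(txs, key=lambda t: t.transcript_id):
        L = len(tx.sequence)
        if L < read_len:
            log.warning(
                "transcript %s (len %d) shorter than read length %d — skipped",
                tx.transcript_id, L, read_len,
            )
            continue
        starts = rng.integers(0, L - read_len + 1, size=n_per_tx)
        for s in starts:
            s = int(s)
            reads.append(SimulatedRead(tx.transcript_id, s, tx.sequence[s:s + read_len]))
    return reads


def _exact_substring_mapper(
    reads: Sequence[SimulatedRead], txs: Sequence[TranscriptSequence]
) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for tx in txs:
        seq = tx.sequence
        for read in reads:
            if read.sequence in seq:
                key = (read.origin_tx, tx.transcript_id)
                counts[key] = counts.get(key, 0) + 1
    return counts


def map_simulated(
    reads: Sequence[SimulatedRead],
    txs: Sequence[TranscriptSequence],
    mapper: Callable[[Sequence[SimulatedRead], Sequence[TranscriptSequence]],
                     dict[tuple[str, str], int]] = _exact_substring_mapper,
) -> SharingMatrix:
    """Tally how many reads from each transcript also map to every other.

    A read maps to a transcript iff its sequence occurs exactly as a
    substring (the default mapper); counts(tx, tx) equals the number of reads
    generated from tx.
    """
    counts = mapper(reads, txs)
    n_per_tx = max(
        (counts.get((t.transcript_id, t.transcript_id), 0) for t in txs), default=0
    )
    return SharingMatrix(
        counts=counts,
        reads_per_tx=n_per_tx,
        transcripts=tuple(t.transcript_id for t in txs),
    )


def derive_paralogs(
    m: SharingMatrix,
    ann: GenomeAnnotation,
    share_frac: float = 0.5,
    min_shared_reads: int | None = None,
) -> ParalogSet:
    """Lift transcript-level read sharing to gene-level paralog pairs.

    Transcripts i, j of different genes are "shared" when the larger of the
    two directional sharing fractions reaches ``share_frac`` (or, if
    ``min_shared_reads`` is given, when either directional count reaches that
    absolute number).  A gene pair is paralogous iff any cross-gene transcript
    pair is shared.
    """
    if not 0.0 < share_frac <= 1.0:
        raise ValueError("share_frac must be in (0, 1]")
    out = ParalogSet()
    gene_of = {t: ann.transcripts[t].gene_id for t in m.transcripts
               if t in ann.transcripts}
    for (tx_i, tx_j), n in m.counts.items():
        if tx_i == tx_j:
            continue
        gi, gj = gene_of.get(tx_i), gene_of.get(tx_j)
        if gi is None or gj is None or gi == gj:
            continue
        if min_shared_reads is not None:
            shared = n >= min_shared_reads
        else:
            shared = max(m.fraction(tx_i, tx_j), m.fraction(tx_j, tx_i)) >= share_frac
        if shared:
            out.add(gi, gj)
    return out


def detect_paralogs(
    txs: Iterable[TranscriptSequence],
    ann: GenomeAnnotation,
    n_per_tx: int = 10_000,
    read_len: int = 100,
    share_frac: float = 0.5,
    seed: int = 0,
) -> ParalogSet:
    """End-to-end: simulate, map, and derive the gene-level paralog set."""
    txs = list(txs)
    reads = simulate_reads(txs, n_per_tx, read_len=read_len, seed=seed)
    matrix = map_simulated(reads, txs)
    return derive_paralogs(matrix, ann, share_frac=share_frac)


def filter_paralog_candidates(
    candidates: Iterable[FusionGeneCandidate], p: ParalogSet
) -> list[FusionGeneCandidate]:
    """Flag candidates whose gene pair is in the paralog set."""
    out = []
    for c in candidates:
        if p.contains(c.gene_a, c.gene_b):
            c.filter_flags.add("paralog")
        out.append(c)
    return out
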