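"""End-to-end orchestration: extract evidence, build FEQs, aggregate
candidates, run the filter cascade, and write the fusion call table.

Also provides call-set comparison (2x2 concordance between two per-sample
binary call sets) used to benchmark the caller against an orthogonal
procedure such as manual IGV curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .annotation import GenomeAnnotation, parse_gtf
from .config import Config
from .feq_core import (
    EmptyFeqError,
    FusionGeneCandidate,
    build_feq,
    candidates_from_evidence,
    merge_feqs,
)
from .filtering import apply_filters
from .paralog_sim import ParalogSet, detect_paralogs, load_transcript_fasta
from .read_extraction import scan_alignments

log = logging.getLogger(__name__)

_COLUMNS = [
    "gene_a", "gene_b", "chrom_a", "pos_a", "chrom_b", "pos_b",
    "n_discordant", "n_split", "n_total", "orientation",
]


@dataclass
class FusionCallTable:
    """Final fusion calls plus provenance for the output header."""

    rows: list[FusionGeneCandidate]
    rejected: list[FusionGeneCandidate] = field(default_factory=list)
    config_hash: str = ""
    inputs: tuple[str, ...] = ()

    def __post_init__(self):
        self.rows.sort(key=lambda c: (-c.n_total, c.gene_a, c.gene_b))

    def to_dataframe(self, rejected: bool = False) -> pd.DataFrame:
        rows = self.rejected if rejected else self.rows
        data = [
            {
                "gene_a": c.gene_a, "gene_b": c.gene_b,
                "chrom_a": c.chrom_a, "pos_a": c.pos_a,
                "chrom_b": c.chrom_b, "pos_b": c.pos_b,
                "n_discordant": c.n_discordant, "n_split": c.n_split,
                "n_total": c.n_total, "orientation": c.orientation,
            }
            | ({"filter_flags": ",".join(sorted(c.filter_flags))} if rejected else {})
            for c in rows
        ]
        cols = _COLUMNS + (["filter_flags"] if rejected else [])
        return pd.DataFrame(data, columns=cols)

    def write_tsv(self, path: str | Path, rejected: bool = False) -> None:
        df = self.to_dataframe(rejected=rejected)
        with open(path, "w") as fh:
            fh.write(f"# fuseqwes {__version__}\n")
            fh.write(f"# config_hash: {self.config_hash}\n")
            for p in self.inputs:
                fh.write(f"# input: {p}\n")
            df.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    bam: str | Path,
    gtf: str | Path | GenomeAnnotation,
    cfg: Config | None = None,
    tx_fasta: str | Path | None = None,
    paralogs: ParalogSet | None = None,
) -> FusionCallTable:
    """Run the full detection workflow on one alignment file.

    ``gtf`` may be a path or an already-parsed annotation.  Paralog filtering
    uses ``paralogs`` when given, otherwise runs the read-sharing simulation
    on ``tx_fasta`` when provided, otherwise is skipped (empty set).
    """
    cfg = cfg or Config()
    ann = gtf if isinstance(gtf, GenomeAnnotation) else parse_gtf(gtf)

    pairs, splits = scan_alignments(bam, ann, cfg)

    feqs = []
    for p in pairs:
        try:
            feqs.append(build_feq(p, ann))
        except EmptyFeqError as exc:
            log.warning("dropping pair without transcript overlap: %s", exc)
    feqs = merge_feqs(feqs)
    candidates = candidates_from_evidence(feqs, splits, ann)

    if paralogs is None:
        if tx_fasta is not None:
            txs = load_transcript_fasta(tx_fasta)
            paralogs = detect_paralogs(
                txs, ann,
                n_per_tx=cfg.sim_reads_per_tx,
                read_len=cfg.read_len,
                share_frac=cfg.paralog_share_frac,
                seed=cfg.seed,
            )
        else:
            paralogs = ParalogSet()

    passed, rejected = apply_filters(candidates, splits, ann, paralogs, cfg)
    inputs = tuple(
        str(x) for x in (bam, gtf, tx_fasta)
        if x is not None and not isinstance(x, GenomeAnnotation)
    )
    return FusionCallTable(
        rows=passed, rejected=rejected, config_hash=cfg.hash(), inputs=inputs
    )


def summarize_support(n_discordant: int, n_split: int) -> int:
    """Total support = discordant read-pair units + split-read units."""
    if n_discordant < 0 or n_split < 0:
        raise ValueError("support counts must be >= 0")
    return n_discordant + n_split


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 agreement between two binary call sets over one sample universe."""

    a: str
    b: str
    tp: int    # positive in both
    fp: int    # positive in b only
    fn: int    # positive in a only
    tn: int    # negative in both

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def agreement_fraction(self) -> Fraction:
        return Fraction(self.tp + self.tn, self.total)

    @property
    def agreement(self) -> int:
        """Agreement percentage rounded to the nearest integer for display."""
        return round(100 * self.agreement_fraction)


def compare_callsets(
    calls_a: Mapping[str, bool],
    calls_b: Mapping[str, bool],
    label_a: str = "a",
    label_b: str = "b",
) -> ConcordanceTable:
    """2x2 concordance of two per-sample binary call sets.

    Both call sets must cover exactly the same samples; a mismatch raises
    with the differing sample names listed.
    """
    only_a = set(calls_a) - set(calls_b)
    only_b = set(calls_b) - set(calls_a)
    if only_a or only_b:
        raise ValueError(
            f"sample universes differ: only in {label_a}: {sorted(only_a)}; "
            f"only in {label_b}: {sorted(only_b)}"
        )
    tp = fp = fn = tn = 0
    for sample, a in calls_a.items():
        b = calls_b[sample]
        if a and b:
            tp += 1
        elif not a and b:
            fp += 1
        elif a and not b:
            fn += 1
        else:
            tn += 1
    return ConcordanceTable(a=label_a, b=label_b, tp=tp, fp=fp, fn=fn, tn=tn)


def concordance_from_counts(tp: int, fp: int, fn: int, tn: int,
                            label_a: str = "a", label_b: str = "b") -> ConcordanceTable:
    """Build a concordance table directly from 2x2 counts."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be >= 0")
    return ConcordanceTable(a=label_a, b=label_b, tp=tp, fp=fp, fn=fn, tn=tn)


def read_calls_tsv(path: str | Path) -> dict[str, bool]:
    """Read a per-sample binary call list: two columns, sample and 0/1."""
    out: dict[str, bool] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("sample"):
                continue
            sample, val = line.split("\t")[:2]
            out[sample] = val.strip() in {"1", "true", "True", "+"}
    return out
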