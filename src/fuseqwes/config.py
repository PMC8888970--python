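"""Pipeline configuration: every detection and filtering threshold in one place.

Defaults follow the published method: MAPQ >= 30 for every alignment segment,
fusion partners restricted to the canonical chromosomes, protein-coding genes
only, a 10 kb minimum intra-chromosomal gene distance, at least one supporting
read pair, at most two genes per split read, a strictly-greater-than-20-base
non-overlap rule for overlapping split mates, and 10,000 simulated reads per
transcript for paralog detection.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def _default_chroms() -> frozenset[str]:
    names = [str(i) for i in range(1, 23)] + ["X", "Y"]
    return frozenset(names)


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so chr15 and 15 compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class Config:
    """Thresholds governing evidence extraction, filtering and simulation."""

    min_mapq: int = 30
    allowed_chroms: frozenset[str] = field(default_factory=_default_chroms)
    require_protein_coding: bool = True
    assume_coding: bool = False          # treat biotype "unknown" as coding
    min_gene_distance: int = 10_000      # bp, nearest-edge gap, inclusive
    min_support: int = 1                 # deduplicated read-pair units
    max_genes_per_split: int = 2
    min_split_nonoverlap: int = 20       # bp, strict: >20 passes
    min_clip_len: int = 20               # bp of soft-clip to call a split
    sim_reads_per_tx: int = 10_000
    paralog_share_frac: float = 0.5
    read_len: int = 100
    keep_duplicates: bool = False
    require_split: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = (
            "min_mapq", "min_gene_distance", "min_support",
            "max_genes_per_split", "min_split_nonoverlap", "min_clip_len",
            "sim_reads_per_tx", "read_len",
        )
        for name in numeric:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.allowed_chroms:
            raise ValueError("allowed_chroms must be non-empty")
        if not 0.0 < self.paralog_share_frac <= 1.0:
            raise ValueError("paralog_share_frac must be in (0, 1]")
        # normalize the whitelist once
        object.__setattr__(
            self, "allowed_chroms",
            frozenset(normalize_chrom(c) for c in self.allowed_chroms),
        )

    def replace(self, **kwargs) -> "Config":
        d = asdict(self)
        d.update(kwargs)
        return Config(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allowed_chroms"] = sorted(d["allowed_chroms"])
        return d

    def hash(self) -> str:
        """Stable digest of all thresholds, for output-table provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Load a YAML (or ``key: value``) config file; keys match field names."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "allowed_chroms" in data:
            data["allowed_chroms"] = frozenset(str(c) for c in data["allowed_chroms"])
        return cls(**data)
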