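# fuseqwes

Fusion-gene detection from DNA alignments (whole-exome or targeted-panel
sequencing), using discordant read pairs and split reads as evidence,
fusion equivalence classes over transcript annotations, a cascade of
biological plausibility filters, and a simulation-based paralog filter.

## Scientific problem

Gene fusions are oncogenic driver events created by structural
rearrangements that join two genes. They are routinely detected from
RNA-seq, but many clinical samples only have DNA available — typically
whole-exome (WES) or targeted-panel libraries. In DNA, a fusion leaves two
kinds of footprints in a paired-end alignment against the reference
genome:

- **Discordant pairs** — the two mates of a fragment align inside two
  *different* genes, because the fragment straddles the genomic junction.
- **Split reads** — a single read crosses the junction, so the aligner
  reports a soft-clipped primary alignment in one gene plus a
  supplementary alignment (linked by the `SA` tag) in the other gene.
  Split reads localise the breakpoint to base resolution.

The difficulty is that WES/panel data are sparse outside capture targets
and riddled with artefacts: low-quality mappings, reads landing in
paralogous genes, read-through of neighbouring genes, and decoy/patch
contigs. `fuseqwes` turns raw alignments into a ranked table of fusion
gene candidates while filtering these failure modes explicitly.

## Method in brief

For paired-end alignments (SAM/BAM) and a gene annotation (GTF):

1. **Read extraction** (`read_extraction`). Records that are unmapped,
   secondary, duplicate, or below MAPQ 30 are discarded (the MAPQ gate
   applies to both mates and to supplementary alignments). A pair whose
   mates overlap disjoint gene sets is a discordant pair; a primary
   alignment with a soft clip of ≥ 20 bases plus a supplementary
   alignment, together touching ≥ 2 genes, is a split read.

2. **Fusion equivalence classes** (`feq_core`). Each piece of evidence is
   mapped to the set of *fusion transcripts* it supports: the Cartesian
   product of the transcripts overlapping mate A and mate B, restricted
   to cross-gene combinations. Evidence with identical transcript-pair
   sets is merged into one fusion equivalence class (FEQ); FEQs are then
   aggregated per gene pair into candidates. A read that contributes both
   split and discordant evidence is counted once, as a split read. The
   breakpoint is the (lower) median of split-read junctions, or the
   innermost mate ends when only discordant pairs exist.

3. **Filter cascade** (`filtering`). Candidates must (a) lie on
   chromosomes 1–22, X, Y; (b) join two protein-coding genes; (c) if
   intra-chromosomal, have a gene-to-gene gap of ≥ 10 kb (read-through
   guard); (d) retain ≥ 1 supporting read after split-read hygiene:
   splits touching > 2 genes are dropped, and when both mates of a pair
   are split, their reference footprints must differ by > 20 bases
   (|union| − |intersection|).

4. **Paralog filter** (`paralog_sim`). Error-free reads (default
   10,000 per transcript) are simulated uniformly from each transcript
   sequence and mapped back by exact substring search. Gene pairs where
   ≥ 50% of one gene's reads also map to the other are recorded as
   paralogous, and candidate fusions between them are rejected.

5. **Synthetic data** (`fixtures`). A generator builds a toy genome and
   annotation, plants a fusion at chosen breakpoints with a chosen tumour
   fraction and coverage, emits a valid SAM with correct split-read
   representation (soft clip + supplementary + reciprocal `SA` tags), and
   returns per-read ground-truth labels. Pair-atomic, nested subsampling
   and a sensitivity-curve harness support coverage-titration studies.

See [docs/methods.md](docs/methods.md) for definitions, parameters, and
design decisions.

## Worked example

Simulate a 150× library with a planted inter-chromosomal G1–G2 fusion at
50% tumour fraction, then call fusions on it:

```sh
$ fuseqwes simulate --outdir demo --coverage 150 --seed 11
wrote demo/planted.sam: 162 split, 113 spanning pairs

$ fuseqwes call --bam demo/planted.sam --gtf demo/genes.gtf -o demo/calls.tsv
1 fusion gene(s) written to demo/calls.tsv

$ cat demo/calls.tsv
# fuseqwes 0.1.0
# config_hash: 0dc1af0e2d5e
# input: demo/planted.sam
# input: demo/genes.gtf
gene_a	gene_b	chrom_a	pos_a	chrom_b	pos_b	n_discordant	n_split	n_total	orientation
G1	G2	chr1	21500	chr2	21500	133	115	248	a_upstream
```

The single call is the planted fusion; `pos_a`/`pos_b` are exactly the
planted breakpoints, with total support 248 = 133 discordant pairs +
115 split reads. (115 < the 162 planted junction-crossing reads because
reads whose clipped portion is shorter than 20 bases are not credited as
split evidence — they surface as discordant pairs instead, which is why
133 > the 113 planted spanning pairs.)

The same pipeline is available programmatically:

```python
from fuseqwes import Config, run_pipeline
table = run_pipeline("demo/planted.sam", "demo/genes.gtf", Config())
for c in table.rows:
    print(c.gene_a, c.gene_b, c.n_total, c.orientation)
```

Other commands: `fuseqwes subsample` (deterministic, pair-atomic, nested
downsampling of a SAM/BAM), `fuseqwes compare` (2×2 concordance between
two per-sample call sets), and `fuseqwes call --sim-paralogs` (derive the
paralog list on the fly from a transcript FASTA).

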