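# Methods

This note defines the model implemented by `fuseqwes`, its parameters,
and the numerical and design choices made where a specification admits
more than one reasonable reading. All coordinates in the package are
1-based and inclusive; SAM's 0-based half-open coordinates are converted
at the I/O boundary and nowhere else.

## Evidence model

Let an annotation consist of genes g with chromosome, span
[start(g), end(g)], strand and biotype, and transcripts t(g) with exon
lists. A read alignment is assigned to every gene whose *genomic span*
(introns included) it overlaps. Span-level assignment is deliberate: DNA
breakpoints fall in introns as often as exons, so exon-level assignment
would discard most true evidence.

**Quality gates.** Unmapped, secondary and duplicate records are removed.
Every alignment considered as evidence — both mates of a pair, and
supplementary alignments of a split read — must have MAPQ ≥ `min_mapq`
(default 30).

**Discordant pair.** A primary pair (r1, r2) is discordant when the gene
sets G(r1) and G(r2) are both non-empty and disjoint. Pairs sharing a
gene are concordant; pairs with an intergenic or low-MAPQ mate are
unassigned and ignored.

**Split read.** A primary alignment with a terminal soft clip of
≥ `min_clip_len` bases (default 20) together with a supplementary
alignment of the same read (the aligner's `SA` representation) is a split
read if the two segments jointly overlap ≥ 2 distinct genes. The junction
on the primary side is the reference position at the clip boundary
(reference end for a right clip, start for a left clip); on the
supplementary side it is the facing end of the supplementary segment.

**Deduplication.** Evidence is counted once per template: one discordant
unit per read name, one split unit per (read name, mate index, gene-pair
set).

## Fusion equivalence classes

Evidence e with mates (or segments) A and B supports the fusion
transcripts

  FT(e) = { (a, b) : a ∈ Tx(G(A)), b ∈ Tx(G(B)), gene(a) ≠ gene(b),
            span(a) ∩ A ≠ ∅, span(b) ∩ B ≠ ∅ }

i.e. the cross-gene Cartesian product of the transcripts each side
touches. Two mates hitting 2 and 3 transcripts therefore yield
|FT| = 2 × 3 = 6 fusion transcripts. Evidence items with identical FT
sets form one *fusion equivalence class* (FEQ); merging FEQs unions their
supporting read names, so total support is conserved. FEQs are then
aggregated per unordered gene pair into candidates with

  n_total = n_discordant + n_split,

where a read contributing both kinds of evidence is counted once, in the
split tally (per gene pair: discordant names minus split names).

**Breakpoint estimate.** With split evidence, the reported position per
gene side is the lower median of the split junctions (median-low: for an
even count the smaller middle value is taken, keeping the estimate an
observed junction). With discordant-only evidence, the *innermost mate
ends* are reported: the maximum alignment end among side-A mates and the
minimum start among side-B mates — the tightest interval the fragments
bound. Genes are reported in canonical order by (chromosome, position);
orientation (`a_upstream` / `b_upstream` / `unknown`) is inferred by
majority vote over split reads from clip side × strand.

## Filter cascade

Applied in order; a candidate records every filter it fails.

| filter | rule | default |
|---|---|---|
| chromosome | both genes on 1–22, X, Y (`chr` prefix normalised) | fixed whitelist |
| biotype | both genes protein-coding; unknown biotype fails unless `assume_coding` | required |
| distance | intra-chromosomal pairs need nearest-edge gap ≥ `min_gene_distance` (inclusive: a 10 000-base gap passes, 9 999 fails); inter-chromosomal pairs pass | 10 kb |
| split hygiene | splits overlapping > `max_genes_per_split` genes are dropped; when both mates of one pair are split, their reference footprints must satisfy \|union\| − \|intersection\| > `min_split_nonoverlap` (strict: 21 passes, 20 fails) | 2 genes, 20 bases |
| support | n_total ≥ `min_support`, *after* removing reads whose split evidence was rejected by hygiene — discarded splits cannot rescue support | 1 |
| require_split | optionally reject discordant-only candidates | off |
| paralog | reject pairs present in the paralog set | — |

The distance filter measures the gap between the nearest gene edges, not
midpoints; overlapping genes have gap 0 and fail. The non-overlap metric
\|union\| − \|intersection\| over reference footprints counts the bases by
which the two mates' evidence differs; identical footprints give 0
(duplicate-like, rejected), disjoint footprints trivially pass.

## Paralog simulation

For each transcript, `sim_reads_per_tx` (default 10,000) error-free reads
of length `read_len` (default 100) are drawn with uniformly random start
positions (transcripts shorter than the read length are skipped with a
warning). Reads are mapped back by exact substring search against all
transcript sequences — exact matching is the point, since paralogy here
means *sequence identity sufficient to confuse a mapper*, and an
error-free read maps wherever its sequence occurs. For genes (u, v) the
directional sharing fraction is

  f(u → v) = (reads simulated from u that also map into v) / (reads simulated from u)

lifted from transcripts to genes by summation. The pair is paralogous
when max(f(u → v), f(v → u)) ≥ `paralog_share_frac` (default 0.5).
The 0.5 default marks pairs where a mapper would misplace reads more
often than chance while tolerating short shared domains; the threshold
is exposed, and an absolute `min_shared_reads` alternative exists. The
mapper is an injectable hook so a real aligner can replace the substring
oracle.

## Synthetic data generator

`make_toy_reference` builds a deterministic toy genome: n genes (default
4) of alternating exon/intron blocks on 1–2 chromosomes, two transcripts
each (full exon set, and one with an interior exon dropped), with options
for an exact duplicated gene pair (paralogy positive control), noncoding
biotypes, and custom chromosome names.

`plant_fusion_reads` emulates a paired-end DNA library over the padded
footprints of the two fusion partners plus a fused allele
A[..break_a] + B[break_b..]:

- The total pair budget is coverage × footprint / (2 × read length), so
  *coverage* means mean depth over the simulated regions. `fraction` is
  the share of pairs drawn from the fused allele (tumour fraction); the
  wild-type remainder is split between the two regions by length.
- Fragment lengths are Gaussian (mean 350, sd 50); reads are error-free
  by default with an optional per-base substitution rate.
- A read crossing the junction with ≥ `min_clip` bases on both sides is
  emitted as the aligner would report it: a soft-clipped primary on the
  longer side plus a supplementary on the other, with reciprocal `SA`
  tags, MAPQ 60, and SEQ in reference orientation. Reads crossing with
  less than `min_clip` overhang are emitted aligned to the longer side
  only — such reads are *not* recoverable as split evidence, and the
  ground-truth object reports the recoverable count separately.
- Per-read labels (`fusion-split`, `fusion-spanning-pair`, `background`)
  form the ground truth for sensitivity studies.

The generator does **not** emulate: sequencing error profiles, base
qualities, capture-efficiency bias, GC bias, chimeric artefacts, PCR
duplicates, or mapper-specific MAPQ behaviour. It produces the *ideal
alignment* of reads from a known genome, which is the right level for
testing the caller's logic rather than the mapper.

**Subsampling.** `subsample_alignments` keeps a read pair iff
md5(seed ":" name) / 2⁶⁴ < fraction. This is deterministic, pair-atomic
(all records of a template kept or dropped together), and *nested*: under
one seed, the 1% subset is a subset of the 5% subset, so support counts
along a titration ladder are non-increasing by construction, isolating
the effect of depth from resampling noise.

## Parameters

| name | default | unit | rationale |
|---|---|---|---|
| `min_mapq` | 30 | phred-scaled | excludes multi-mapping placements (< 1/1000 error) |
| `min_clip_len` | 20 | bases | minimum unique anchor for a split segment |
| `min_gene_distance` | 10 000 | bases | suppresses read-through between neighbouring genes |
| `min_support` | 1 | read units | panels are shallow off-target; rank by support instead |
| `max_genes_per_split` | 2 | genes | splits touching 3+ genes are ambiguous mappings |
| `min_split_nonoverlap` | 20 | bases | both-mates-split pairs must carry non-redundant evidence |
| `sim_reads_per_tx` | 10 000 | reads | sharing-fraction standard error ≤ 0.005 |
| `paralog_share_frac` | 0.5 | fraction | majority of reads confusable → unreliable locus |
| `read_len` | 100 | bases | typical short-read WES |

All thresholds live in a frozen `Config` whose `hash()` (12 hex chars of
a SHA-1 over the sorted parameter JSON) is stamped into every output
table for provenance.

## Determinism

Every stochastic routine takes an explicit seed and uses
`numpy.random.default_rng`; derived seeds are reduced modulo 2³¹. Output
tables are sorted (descending total support, then gene pair) and written
byte-identically across runs.

## Limitations

- Gene assignment by genomic span cannot distinguish a fusion from a
  structural variant with both ends inside the same two genes but no
  expressed chimeric product; DNA evidence alone never can.
- No orientation consistency constraint is enforced between split reads
  and discordant pairs; orientation is reported, not filtered on, since
  panel-depth data often yields too few reads for a reliable vote.
- The exact-substring paralog mapper ignores near-identical (mismatched)
  paralogs; with error-free reads this is conservative, and the mapper
  hook allows substituting an aligner that models mismatches.
- Breakpoints from discordant-only evidence are interval bounds, not
  base-resolution positions.
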