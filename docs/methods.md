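# Methods

## Model of the data

The filter targets data from restriction-enzyme-based target enrichment
(Haloplex and similar PCR/amplicon chemistries). Because fragments are
generated at reproducible restriction sites and then amplified, reads
enriched from a genuine amplicon share its exact genomic boundaries.
Three consequences drive the design:

1. overlapping theoretical amplicons are *independent captures* of the
   same locus, so a true variant should recur across them;
2. a fragment whose boundaries match no design record ("aspecific") is
   a known artefact source and must not contribute amplicon-level
   support;
3. PCR duplicates are indistinguishable from independent molecules
   without molecular barcodes, so they are retained, and read depth is
   interpreted accordingly (the amplicon fraction, not raw depth, is the
   primary reliability signal).

## Procedure

For each (variant, ALT allele) pair:

1. **Pileup.** Reads overlapping the site with MAPQ ≥ `min_mapq` are
   collected; unmapped, secondary, supplementary and QC-fail records are
   excluded, duplicates retained.
2. **Allele call.** SNVs compare the aligned base (base quality ≥
   `min_baseq`, else the read is uncalled); insertions require the stated
   inserted sequence immediately after the anchor base; deletions require
   exactly the stated span to be deleted; MNVs compare the contiguous
   aligned segment. Reads that cannot resolve the event (site inside a
   read deletion/skip, alignment ending inside the event) are uncalled
   and excluded from depth.
3. **Amplicon assignment.** The read's fragment span — the pair's outer
   span for proper pairs, recovered from TLEN, otherwise the read's
   aligned span — is matched against the design amplicons covering the
   position: the candidate minimizing the summed boundary offset wins,
   provided both offsets are ≤ `assignment_tolerance`; ties break by
   design-file order; otherwise the read is aspecific.
4. **Aggregation.** `AmpC` = design amplicons covering the position
   (design-theoretical: an amplicon that captured no reads still dilutes
   confidence); `AmpCA`/`AmpCR` = covering amplicons with ≥1 assigned
   ALT/REF read; an amplicon "contains" an allele from a single read
   upward. Read-end ALT support counts ALT reads whose variant lies
   within `min_read_pos` bases of the physical 5' or 3' read end
   (orientation-resolved, soft clips excluded).
5. **Classification.** The ordered decision tree (see README) assigns
   the first matching category. `OneAmpPass` and `MatchAmpPass` are
   terminal: they mark design limitations rather than quality tiers, and
   later rules are not applied to them.

## Parameters

| key | default | unit | role |
|---|---|---|---|
| `min_depth`, `min_depth_tumor`, `min_depth_normal` | 10 | reads | depth floors; 10 is a conservative panel-sequencing floor chosen here (the rule itself is standard, the value is configurable) |
| `min_read_pos` | 2 | bases | read-end window for positional artefacts |
| `min_read_pos_fraction` | 10 | % | strict threshold on end-positioned ALT reads over all reads |
| `min_frac` | 1 | % | strict threshold on normal-sample ALT fraction (somatic); raise to tolerate field cancerization |
| `assignment_tolerance` | 2 | bases | boundary slack absorbing adapter-trimming jitter at reproducible restriction boundaries |
| `min_baseq` | 13 | phred | conventional pileup base-quality floor |
| `min_mapq` | 20 | phred | conventional pileup mapping-quality floor |

## Design choices made where the design was open

- **Zero supporting amplicons.** The published rule texts for 2 and >2
  covering amplicons address positive support counts; a site with
  `AmpCA = 0` (e.g. ALT only in aspecific fragments) is classified
  `LowAmpFail` for any `AmpC`, and an off-design site (`AmpC = 0`) is
  likewise failed with a logged warning rather than given its own
  category.
- **Somatic depth order.** Tumor depth is checked before normal depth.
- **Offsets.** `AmpF_OA = AmpFA − alt_depth/depth` (and the REF
  analogue): the signed difference between amplicon-level and read-level
  support, 0 for degenerate evidence. The one-line published field
  description admits other readings; this reconstruction is the simplest
  quantity with the stated meaning.
- **Multi-allelic records.** Each ALT is classified independently; the
  record FILTER is the most severe per-allele category (Depth* >
  LowAmpFail > PositionFail > NormalFail > OneAmpPass > MatchAmpPass >
  AmpPass) and per-allele categories are kept in INFO `AmpCat`.
- **FILTER replacement.** The verdict replaces the upstream FILTER; the
  original value is preserved in INFO `OrigFilter`.
- **Coordinates.** BED is 0-based half-open; VCF positions are converted
  to 0-based before design queries. Chromosome names are matched by
  exact string equality (a warning is logged for chromosomes absent from
  the design) — silent `chr`-prefix coercion would hide real
  design/reference mismatches.
- **Counting unit.** Depth counts reads, not fragments; both mates of an
  overlapping pair contribute allele observations while sharing the
  pair-level amplicon assignment.

## Numerical and degenerate-input conventions

Fractions are guarded: `AmpFA = AmpFR = 0` when `AmpC = 0`, end/normal
fractions are 0 at zero depth, offsets are 0 at zero depth or zero
`AmpC`. Serialized fractions carry 4 decimal places. Threshold
comparisons at the fraction rules are strict inequalities, so values
exactly at a threshold pass; depth rules use strict `<` against the
floor. Output is re-serialized from parsed columns, making the VCF
byte-stable across runs and thread counts; parallel runs partition the
record list into contiguous blocks and reassemble in input order, which
is sound because each variant's verdict depends only on its own
evidence.

## Synthetic data generator

The generator (`amplifilter.fixtures`) emits matched reference
FASTA / design BED / sorted+indexed BAM(s) / VCF / truth-table TSV on a
10 kb-scale synthetic contig `chrS`, one scenario per kilobase. Each
scenario specifies covering amplicons as (lead, tail) distances from the
variant and per-amplicon (REF, ALT) read counts; reads are single-end,
error-free outside planted alleles (base quality Q40, MAPQ 60), with
spans equal to their amplicon's boundaries, or shifted by 7 bp for
aspecific pools. Every scenario is validated against the decision tree
at generation time, so the truth table is exact by construction.
Canonical specs cover all nine FILTER labels (somatic: 9 scenarios;
germline: 6); randomized specs draw feasible profiles from a seeded
generator and derive their intended category from the exact expected
evidence. Planted variants are SNVs; indel allele calling is exercised
by unit tests on in-memory alignments instead.

What passing these fixtures shows: the read-walk, allele calling,
assignment, aggregation and classification chain recovers designed
evidence exactly and deterministically. What it does not show: behaviour
under sequencing error, coverage unevenness, mapping ambiguity,
paired-end fragment-size variation or real panel designs — the generator
deliberately models none of these.

## Problem sizes used in checks

The shipped verification runs use desk-scale inputs chosen to make the
properties exhaustive rather than statistical: an exhaustive
threshold-straddling grid of evidence states against an independently
hand-coded rule table; canonical fixtures plus 100 (tests) / 60
(acceptance script) seeded randomized fixtures of ~3 variants each; and
a 10⁴-interval random design queried at 10³ positions against a linear
scan.

## Known limitations

- Somatic evidence comes entirely from the two BAMs; VCF sample columns
  are passed through untouched and never interpreted.
- Symbolic/structural ALTs (`<DEL>`, breakends) are passed through
  unclassified with FILTER untouched.
- No local realignment or base-quality recalibration; allele calling
  trusts the aligner's CIGAR, so indels shifted by alignment ambiguity
  may be called OTHER.
- Amplicon assignment assumes trimmed reads whose fragment boundaries
  approximate restriction sites; untrimmed adapters inflate aspecific
  calls.
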