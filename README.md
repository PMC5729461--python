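# amplifilter

Amplicon-aware variant filtering for PCR/amplicon-based targeted
resequencing panels (Haloplex-style target enrichment).

## The problem

Restriction-fragment enrichment produces *vertical read blocks*: stacks
of reads sharing the exact start/end coordinates of the theoretical
amplicons listed in the assay design. The wet-lab chemistry also
produces recurrent artefacts that ordinary variant callers cannot see,
because caller quality scores carry no amplicon information:

- **aspecific fragments** — enriched fragments whose boundaries match no
  predicted restriction fragment; variants supported only by such
  fragments are spurious;
- **read-end errors** — alternative alleles confined to the first bases
  of the physical 5'/3' read ends, a systematic enrichment artefact;
- **low amplicon redundancy** — a true variant should recur across the
  independently captured amplicons that overlap its position;
- **PCR duplicates** — inherent to the technology and not removable
  without molecular barcodes, so depth alone overstates evidence.

`amplifilter` post-processes a called VCF together with the alignment
file(s) and the amplicon design BED. For every candidate variant it
assigns each overlapping read (or proper read pair, via its outer
fragment span) to a theoretical amplicon or marks it aspecific, then
computes the **amplicon fraction**

    AmpFA = AmpCA / AmpC

where `AmpC` is the number of theoretical amplicons covering the
position and `AmpCA` the number of them containing at least one
ALT-supporting read. Each variant is assigned to the **first matching
category** of an ordered decision tree:

| order | category | rule (defaults) |
|---|---|---|
| 1 | `DepthFail` / `DepthFailTumor` / `DepthFailNormal` | depth < 10 reads (germline / tumor / normal) |
| 2 | `OneAmpPass` | covered by and present in a single theoretical amplicon (terminal) |
| 3 | `LowAmpFail` | >2 covering amplicons with ALT in <3 of them; 2 covering with ALT in ≤1; or no genuine amplicon support |
| 4 | `MatchAmpPass` | exactly 2 covering amplicons, ALT in both (terminal) |
| 5 | `PositionFail` | >10% of all reads carry ALT within 2 bases of a read end |
| 6 | `NormalFail` | somatic only: ALT in >1% of normal-sample reads |
| 7 | `AmpPass` | everything passed |

Comparisons at steps 5–6 are strict (`>`), so a fraction exactly at the
threshold passes. The category is written to FILTER of a VCF v4.1
output (variants are flagged, never removed) and the metrics `AmpFR`,
`AmpFA`, `AmpCR`, `AmpCA`, `AmpC`, `AmpF_OA`, `AmpF_OR` are added to
INFO for downstream selection.

## Usage

```bash
amplifilter somatic  -bn normal.bam -bt tumor.bam -v somatic_variants.vcf \
                     -d amplicon_design.bed -od output_directory
amplifilter germline -b sample.bam -v variants.vcf -d amplicon_design.bed -od out
```

Thresholds are overridden with `-c config.yaml` (keys such as
`min_frac`, `min_depth_tumor`, `min_read_pos_fraction`; unknown keys are
rejected). `-t N` classifies variants in N worker processes; output is
byte-identical for any thread count. `--pass-only` additionally writes a
VCF restricted to the passing categories.

## Worked example

`examples/filter_somatic.py` builds a nine-variant synthetic panel (one
scenario per category) and runs the somatic pipeline:

```
        site  intended         FILTER           INFO (amplicon metrics)
chrS: 1001  DepthFailTumor   DepthFailTumor   AmpFR=1.0000;AmpFA=0.5000;AmpCR=2;AmpCA=1;AmpC=2;AmpF_OA=0.3333;AmpF_OR=0.1667
chrS: 3001  OneAmpPass       OneAmpPass       AmpFR=1.0000;AmpFA=1.0000;AmpCR=1;AmpCA=1;AmpC=1;AmpF_OA=0.6000;AmpF_OR=0.4000
chrS: 4001  LowAmpFail       LowAmpFail       AmpFR=1.0000;AmpFA=0.5000;AmpCR=4;AmpCA=2;AmpC=4;AmpF_OA=0.3000;AmpF_OR=0.2000
chrS: 7001  PositionFail     PositionFail     AmpFR=1.0000;AmpFA=1.0000;AmpCR=3;AmpCA=3;AmpC=3;AmpF_OA=0.7333;AmpF_OR=0.2667
chrS: 9001  AmpPass          AmpPass          AmpFR=1.0000;AmpFA=1.0000;AmpCR=3;AmpCA=3;AmpC=3;AmpF_OA=0.7188;AmpF_OR=0.2812
```

(abridged; the script prints all nine). At chrS:4001 the ALT allele is
present in only 2 of the 4 covering amplicons (`AmpFA=0.5`), so the call
fails the redundancy rule; at chrS:9001 all three amplicons support it
and it passes. `AmpF_OA = AmpFA − alt_depth/depth` exposes disagreement
between amplicon-level and read-level support. The other examples show
per-read evidence behind an aspecific-fragment artefact
(`inspect_site_evidence.py`) and threshold tuning for field
cancerization (`custom_thresholds.py`).

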