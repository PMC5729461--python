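"""Deterministic synthetic fixtures with known ground-truth categories.

The generator emits a matched triple — amplicon-design BED, sorted and
indexed alignment file(s), candidate VCF — plus a machine-readable truth
table, for a list of scenarios that each force one filter category.  It
emulates the geometry of restriction-fragment enrichment: reads from a
genuine amplicon share the amplicon's exact boundaries (vertical read
blocks), aspecific fragments have shifted boundaries matching no design
record, and positional artefacts place the alternative allele within a
couple of bases of the physical read ends.  Reads are single-end,
error-free outside the planted alleles, base quality Q40 and MAPQ 60, so
every scenario's evidence profile is exact by construction; scenarios
are validated against the decision tree at generation time.

It deliberately does not model sequencing error, quality-score decay,
coverage unevenness or paired-end fragment-size variation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pysam

from .config import GERMLINE, SOMATIC, FilterConfig
from .engine import (
    AMP_PASS,
    DEPTH_FAIL,
    DEPTH_FAIL_NORMAL,
    DEPTH_FAIL_TUMOR,
    LOW_AMP_FAIL,
    MATCH_AMP_PASS,
    NORMAL_FAIL,
    ONE_AMP_PASS,
    POSITION_FAIL,
    classify,
)
from .errors import FixtureSpecError
from .evidence import AmpliconEvidence

CONTIG = "chrS"
BASES = "ACGT"
_ASPECIFIC_SHIFT = 7  # bp offset making a fragment match no design record


@dataclass(frozen=True)
class Scenario:
    """One spiked variant site and the read evidence that surrounds it.

    ``amplicons`` gives each covering theoretical amplicon as
    ``(lead, tail)``: the variant sits ``lead`` bases from the fragment
    start and ``tail`` bases before its last base, so every read from
    that amplicon sees the variant at those distances from its ends.
    ``tumor_reads``/``normal_reads`` give ``(n_ref, n_alt)`` per
    amplicon; aspecific read pools use the first amplicon's geometry
    shifted by 7 bp.
    """

    name: str
    category: str
    amplicons: tuple[tuple[int, int], ...]
    tumor_reads: tuple[tuple[int, int], ...]
    normal_reads: tuple[tuple[int, int], ...] | None = None
    tumor_aspecific: tuple[int, int] = (0, 0)
    normal_aspecific: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class FixtureSpec:
    """A reproducible fixture: seed + scenario list + layout constants."""

    seed: int
    mode: str
    scenarios: tuple[Scenario, ...]
    spacing: int = 1000  # bp between scenario sites; bounds read spans

    def __post_init__(self) -> None:
        if self.mode not in (GERMLINE, SOMATIC):
            raise FixtureSpecError(f"unknown mode {self.mode!r}")
        for scenario in self.scenarios:
            _validate_scenario(scenario, self.mode)

    @property
    def contig_length(self) -> int:
        return self.spacing * (len(self.scenarios) + 1) + 500


@dataclass(frozen=True)
class TruthRow:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    category: str
    amp_c: int
    amp_ca: int
    amp_cr: int
    depth: int
    alt_depth: int
    depth_normal: int
    alt_depth_normal: int
    end_alt_reads: int
    aspecific_reads: int


@dataclass(frozen=True)
class FixturePaths:
    reference: Path
    design: Path
    vcf: Path
    bam: Path  # tumor in somatic mode, the single sample in germline mode
    bam_normal: Path | None
    truth: Path


# ---------------------------------------------------------------------------
# expected evidence and validation
# ---------------------------------------------------------------------------


def expected_evidence(scenario: Scenario, sample: str, config: FilterConfig | None = None) -> AmpliconEvidence:
    """The evidence profile the pipeline must recover for one sample."""
    config = config or FilterConfig(mode=GERMLINE)
    reads = scenario.tumor_reads if sample == "tumor" else scenario.normal_reads
    aspecific = scenario.tumor_aspecific if sample == "tumor" else scenario.normal_aspecific
    if reads is None:
        raise FixtureSpecError(f"scenario {scenario.name!r} has no {sample} reads")
    amp_c = len(scenario.amplicons)
    amp_ca = sum(1 for _, n_alt in reads if n_alt > 0)
    amp_cr = sum(1 for n_ref, _ in reads if n_ref > 0)
    depth = sum(n_ref + n_alt for n_ref, n_alt in reads) + sum(aspecific)
    alt_depth = sum(n_alt for _, n_alt in reads) + aspecific[1]
    ref_depth = depth - alt_depth
    end_alt = sum(
        n_alt
        for (lead, tail), (_, n_alt) in zip(scenario.amplicons, reads)
        if lead < config.min_read_pos or tail < config.min_read_pos
    )
    # aspecific fragments are shifted inward at the 5' side; with the
    # layout constraints below they never place the variant at a read end
    return AmpliconEvidence(
        amp_c=amp_c,
        amp_ca=amp_ca,
        amp_cr=amp_cr,
        depth=depth,
        alt_depth=alt_depth,
        ref_depth=ref_depth,
        end_alt_reads=end_alt,
        aspecific_reads=sum(aspecific),
    )


def _validate_scenario(scenario: Scenario, mode: str) -> None:
    n = len(scenario.amplicons)
    if n == 0:
        raise FixtureSpecError(f"scenario {scenario.name!r}: at least one covering amplicon is required")
    if len(scenario.tumor_reads) != n:
        raise FixtureSpecError(f"scenario {scenario.name!r}: one (n_ref, n_alt) pair per amplicon is required")
    if any(r < 0 or a < 0 for r, a in scenario.tumor_reads):
        raise FixtureSpecError(f"scenario {scenario.name!r}: negative read counts")
    for lead, tail in scenario.amplicons:
        if lead < 2 + _ASPECIFIC_SHIFT:
            raise FixtureSpecError(
                f"scenario {scenario.name!r}: lead must be >= {2 + _ASPECIFIC_SHIFT} so aspecific"
                " fragments still cover the site away from read ends"
            )
        if tail < 0:
            raise FixtureSpecError(f"scenario {scenario.name!r}: negative tail")
    # boundary separation must exceed the default assignment tolerance so
    # every genuine read maps to exactly one amplicon
    for i, (l1, t1) in enumerate(scenario.amplicons):
        for l2, t2 in scenario.amplicons[i + 1 :]:
            if abs(l1 - l2) <= 2 and abs(t1 - t2) <= 2:
                raise FixtureSpecError(f"scenario {scenario.name!r}: ambiguous amplicon boundaries")
    config = FilterConfig(mode=mode)
    if mode == SOMATIC:
        if scenario.normal_reads is None or len(scenario.normal_reads) != n:
            raise FixtureSpecError(f"scenario {scenario.name!r}: somatic scenarios need per-amplicon normal reads")
        verdict = classify(expected_evidence(scenario, "tumor", config), expected_evidence(scenario, "normal", config), config)
    else:
        if scenario.normal_reads is not None:
            raise FixtureSpecError(f"scenario {scenario.name!r}: germline scenarios must not define normal reads")
        verdict = classify(expected_evidence(scenario, "tumor", config), None, config)
    if verdict.category != scenario.category:
        raise FixtureSpecError(
            f"scenario {scenario.name!r} does not force its intended category: "
            f"expected {scenario.category}, decision tree gives {verdict.category}"
        )


# ---------------------------------------------------------------------------
# canonical and randomized specs
# ---------------------------------------------------------------------------

_MID3 = ((40, 60), (60, 40), (80, 20))  # three staggered amplicons, variant mid-read
_MID2 = ((40, 60), (60, 40))
_MID1 = ((50, 50),)


def canonical_somatic_spec(seed: int = 11) -> FixtureSpec:
    """Nine scenarios, one per category a somatic run can emit (both depth
    flags and both LowAmpFail variants)."""
    scenarios = (
        Scenario("depth_fail_tumor", DEPTH_FAIL_TUMOR, _MID2, ((3, 1), (2, 0)), ((10, 0), (10, 0))),
        Scenario("depth_fail_normal", DEPTH_FAIL_NORMAL, _MID3, ((7, 3), (7, 3), (7, 3)), ((3, 0), (3, 0), (0, 0))),
        Scenario("one_amp_pass", ONE_AMP_PASS, _MID1, ((9, 6),), ((20, 0),)),
        Scenario("low_amp_fail_many", LOW_AMP_FAIL, ((33, 67), (48, 52), (63, 37), (78, 22)),
                 ((6, 4), (6, 4), (10, 0), (10, 0)), ((8, 0), (8, 0), (8, 0), (8, 0))),
        Scenario("low_amp_fail_two", LOW_AMP_FAIL, _MID2, ((6, 4), (10, 0)), ((12, 0), (12, 0))),
        Scenario("match_amp_pass", MATCH_AMP_PASS, _MID2, ((7, 3), (7, 3)), ((12, 0), (12, 0))),
        Scenario("position_fail", POSITION_FAIL, ((40, 60), (60, 40), (80, 1)),
                 ((9, 1), (9, 1), (4, 6)), ((10, 0), (10, 0), (10, 0))),
        Scenario("normal_fail", NORMAL_FAIL, _MID3, ((7, 3), (7, 3), (7, 3)), ((16, 1), (16, 1), (16, 0))),
        Scenario("amp_pass", AMP_PASS, _MID3, ((7, 3), (7, 3), (7, 3)), ((17, 0), (17, 0), (16, 0)),
                 tumor_aspecific=(2, 0)),
    )
    return FixtureSpec(seed=seed, mode=SOMATIC, scenarios=scenarios)


def canonical_germline_spec(seed: int = 13) -> FixtureSpec:
    """Six scenarios, one per category a germline run can emit."""
    scenarios = (
        Scenario("depth_fail", DEPTH_FAIL, _MID2, ((3, 1), (2, 1))),
        Scenario("one_amp_pass", ONE_AMP_PASS, _MID1, ((9, 6),)),
        Scenario("low_amp_fail_aspecific", LOW_AMP_FAIL, _MID3, ((10, 0), (10, 0), (10, 0)),
                 tumor_aspecific=(0, 5)),
        Scenario("match_amp_pass", MATCH_AMP_PASS, _MID2, ((7, 3), (7, 3))),
        Scenario("position_fail", POSITION_FAIL, ((40, 60), (60, 40), (80, 0)),
                 ((9, 1), (9, 1), (3, 7))),
        Scenario("amp_pass", AMP_PASS, _MID3, ((7, 3), (7, 3), (7, 3))),
    )
    return FixtureSpec(seed=seed, mode=GERMLINE, scenarios=scenarios)


def boundary_strictness_spec(seed: int = 17) -> FixtureSpec:
    """Fractions sitting exactly on the strict thresholds must still pass.

    Scenario one puts the end-position ALT fraction at exactly 10% (5 of
    50 reads); scenario two puts the normal ALT fraction at exactly 1%
    (1 of 100 reads).  Both must come out AmpPass.
    """
    scenarios = (
        Scenario("end_fraction_exactly_10pct", AMP_PASS, ((40, 60), (60, 40), (80, 1)),
                 ((13, 2), (13, 2), (15, 5)), ((15, 0), (15, 0), (15, 0))),
        Scenario("normal_fraction_exactly_1pct", AMP_PASS, _MID3,
                 ((7, 3), (7, 3), (7, 3)), ((33, 1), (33, 0), (33, 0))),
    )
    return FixtureSpec(seed=seed, mode=SOMATIC, scenarios=scenarios)


def random_spec(seed: int, n_scenarios: int = 3, mode: str = SOMATIC) -> FixtureSpec:
    """A seeded randomized spec whose categories are derived, not forced.

    Evidence profiles are drawn at random within the generator's layout
    constraints and each scenario's intended category is whatever the
    decision tree assigns to its exact expected evidence, so end-to-end
    recovery exercises the full read-level extraction path.
    """
    rng = np.random.default_rng(seed)
    config = FilterConfig(mode=mode)
    scenarios = []
    for i in range(n_scenarios):
        amp_c = int(rng.integers(1, 5))
        leads = [20 + 15 * k + int(rng.integers(0, 5)) for k in range(amp_c)]
        tails = [20 + 15 * (amp_c - 1 - k) + int(rng.integers(0, 5)) for k in range(amp_c)]
        if amp_c > 1 and rng.random() < 0.35:
            tails[-1] = int(rng.integers(0, 2))  # one end-positioned amplicon
        amplicons = tuple(zip(leads, tails))
        low_depth = rng.random() < 0.15
        tumor = []
        for _ in range(amp_c):
            if low_depth:
                n_ref, n_alt = int(rng.integers(0, 3)), int(rng.integers(0, 2))
            else:
                n_ref = int(rng.integers(4, 14))
                n_alt = int(rng.integers(0, 8))
            tumor.append((n_ref, n_alt))
        tumor_aspecific = (int(rng.integers(0, 4)), int(rng.integers(0, 3))) if rng.random() < 0.4 else (0, 0)
        normal = None
        if mode == SOMATIC:
            normal_low = rng.random() < 0.1
            normal = []
            for _ in range(amp_c):
                if normal_low:
                    normal.append((int(rng.integers(0, 3)), 0))
                else:
                    normal.append((int(rng.integers(8, 20)), int(rng.integers(0, 2))))
            normal = tuple(normal)
        scenario = Scenario(
            name=f"rand_{seed}_{i}",
            category=AMP_PASS,  # placeholder; replaced with the derived category below
            amplicons=amplicons,
            tumor_reads=tuple(tumor),
            normal_reads=normal,
            tumor_aspecific=tumor_aspecific,
        )
        ev_t = expected_evidence(scenario, "tumor", config)
        ev_n = expected_evidence(scenario, "normal", config) if mode == SOMATIC else None
        scenario = replace(scenario, category=classify(ev_t, ev_n, config).category)
        scenarios.append(scenario)
    return FixtureSpec(seed=seed, mode=mode, scenarios=tuple(scenarios))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _reference_sequence(spec: FixtureSpec) -> str:
    rng = np.random.default_rng(spec.seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, spec.contig_length)])


def _site(spec: FixtureSpec, i: int, ref_seq: str) -> tuple[int, str, str]:
    """(0-based position, REF base, ALT base) for scenario i."""
    pos0 = spec.spacing * (i + 1)
    ref = ref_seq[pos0]
    alt = BASES[(BASES.index(ref) + 1) % 4]
    return pos0, ref, alt


def truth_table(spec: FixtureSpec) -> list[TruthRow]:
    """One row per scenario, matching what :func:`generate` writes."""
    ref_seq = _reference_sequence(spec)
    config = FilterConfig(mode=spec.mode)
    rows = []
    for i, scenario in enumerate(spec.scenarios):
        pos0, ref, alt = _site(spec, i, ref_seq)
        ev = expected_evidence(scenario, "tumor", config)
        if spec.mode == SOMATIC:
            ev_n = expected_evidence(scenario, "normal", config)
            depth_n, alt_n = ev_n.depth, ev_n.alt_depth
        else:
            depth_n, alt_n = 0, 0
        rows.append(
            TruthRow(
                chrom=CONTIG,
                pos=pos0 + 1,
                ref=ref,
                alt=alt,
                category=scenario.category,
                amp_c=ev.amp_c,
                amp_ca=ev.amp_ca,
                amp_cr=ev.amp_cr,
                depth=ev.depth,
                alt_depth=ev.alt_depth,
                depth_normal=depth_n,
                alt_depth_normal=alt_n,
                end_alt_reads=ev.end_alt_reads,
                aspecific_reads=ev.aspecific_reads,
            )
        )
    return rows


def _scenario_reads(spec: FixtureSpec, i: int, scenario: Scenario, sample: str, ref_seq: str):
    """Yield (qname, start0, sequence) for one scenario and sample."""
    pos0, _, alt = _site(spec, i, ref_seq)
    reads = scenario.tumor_reads if sample == "tumor" else scenario.normal_reads
    aspecific = scenario.tumor_aspecific if sample == "tumor" else scenario.normal_aspecific
    pools = []
    for k, ((lead, tail), (n_ref, n_alt)) in enumerate(zip(scenario.amplicons, reads)):
        pools.append((f"s{i}_a{k}", pos0 - lead, lead + tail + 1, n_ref, n_alt))
    lead0, tail0 = scenario.amplicons[0]
    pools.append(
        (f"s{i}_asp", pos0 - lead0 + _ASPECIFIC_SHIFT, lead0 + tail0 + 1, aspecific[0], aspecific[1])
    )
    for tag, start, length, n_ref, n_alt in pools:
        base_seq = ref_seq[start : start + length]
        alt_seq = base_seq[: pos0 - start] + alt + base_seq[pos0 - start + 1 :]
        for j in range(n_ref):
            yield f"{tag}_ref{j}", start, base_seq
        for j in range(n_alt):
            yield f"{tag}_alt{j}", start, alt_seq


def _write_sam_as_bam(sam_lines: list[str], contig_length: int, out_bam: Path) -> None:
    sam_path = out_bam.with_suffix(".sam")
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{CONTIG}\tLN:{contig_length}\n")
        fh.writelines(sam_lines)
    pysam.sort("-o", str(out_bam), str(sam_path))
    pysam.index(str(out_bam))
    sam_path.unlink()


def generate(spec: FixtureSpec, out_dir: str | Path) -> FixturePaths:
    """Write the full fixture set and return the emitted paths.

    Identical ``spec`` (including seed) yields byte-identical text
    outputs and content-identical alignments.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_seq = _reference_sequence(spec)

    ref_path = out_dir / "reference.fa"
    with open(ref_path, "w") as fh:
        fh.write(f">{CONTIG}\n")
        for off in range(0, len(ref_seq), 80):
            fh.write(ref_seq[off : off + 80] + "\n")
    pysam.faidx(str(ref_path))

    bed_lines = []
    for i, scenario in enumerate(spec.scenarios):
        pos0, _, _ = _site(spec, i, ref_seq)
        for k, (lead, tail) in enumerate(scenario.amplicons):
            bed_lines.append((pos0 - lead, pos0 + tail + 1, f"AMP_{i}_{k}"))
    bed_lines.sort()
    design_path = out_dir / "design.bed"
    with open(design_path, "w") as fh:
        for start, end, name in bed_lines:
            fh.write(f"{CONTIG}\t{start}\t{end}\t{name}\n")

    samples = ("tumor", "normal") if spec.mode == SOMATIC else ("tumor",)
    bam_paths = {}
    for sample in samples:
        sam_lines = []
        for i, scenario in enumerate(spec.scenarios):
            for qname, start, seq in _scenario_reads(spec, i, scenario, sample, ref_seq):
                sam_lines.append(
                    f"{qname}\t0\t{CONTIG}\t{start + 1}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t{'I' * len(seq)}\n"
                )
        name = "sample.bam" if spec.mode == GERMLINE else f"{sample}.bam"
        bam_paths[sample] = out_dir / name
        _write_sam_as_bam(sam_lines, spec.contig_length, bam_paths[sample])

    vcf_path = out_dir / "variants.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={CONTIG},length={spec.contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if spec.mode == SOMATIC:
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL\n")
        else:
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for i, scenario in enumerate(spec.scenarios):
            pos0, ref, alt = _site(spec, i, ref_seq)
            if spec.mode == SOMATIC:
                fh.write(f"{CONTIG}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t0/1\t0/0\n")
            else:
                fh.write(f"{CONTIG}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t0/1\n")

    truth_path = out_dir / "truth.tsv"
    rows = truth_table(spec)
    with open(truth_path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tcategory\tamp_c\tamp_ca\tamp_cr\tdepth\talt_depth"
            "\tdepth_normal\talt_depth_normal\tend_alt_reads\taspecific_reads\n"
        )
        for r in rows:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.category}\t{r.amp_c}\t{r.amp_ca}"
                f"\t{r.amp_cr}\t{r.depth}\t{r.alt_depth}\t{r.depth_normal}\t{r.alt_depth_normal}"
                f"\t{r.end_alt_reads}\t{r.aspecific_reads}\n"
            )

    return FixturePaths(
        reference=ref_path,
        design=design_path,
        vcf=vcf_path,
        bam=bam_paths["tumor"],
        bam_normal=bam_paths.get("normal"),
        truth=truth_path,
    )
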