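"""Allele calling, amplicon assignment and evidence aggregation."""

from pathlib import Path

import numpy as np
import pysam
import pytest
from conftest import make_read

from amplifilter import fixtures as fx
from amplifilter.config import FilterConfig
from amplifilter.design import AmpliconRecord, read_design
from amplifilter.evidence import (
    ALT,
    ASPECIFIC,
    OTHER,
    REF,
    UNCALLED,
    AmpliconEvidence,
    aggregate,
    assign_to_amplicon,
    call_allele,
    collect_evidence,
    collect_observations,
    end_distances,
    end_position_alt_fraction,
    fragment_span,
    normal_alt_fraction,
)

GERMLINE_CFG = FilterConfig(mode="germline")


# ---------------------------------------------------------------------------
# allele calling on in-memory reads
# ---------------------------------------------------------------------------


def snv_read(base_at_site, qual_at_site=40):
    seq = list("A" * 50)
    seq[25] = base_at_site
    read = make_read(start=100, cigar="50M", seq="".join(seq))
    quals = pysam.qualitystring_to_array("I" * 50)
    quals[25] = qual_at_site
    read.query_qualities = quals
    return read


@pytest.mark.parametrize(
    "base, expected",
    [("T", ALT), ("C", REF), ("G", OTHER)],
)
def test_snv_allele_classes(base, expected):
    allele, qpos = call_allele(snv_read(base), 125, "C", "T")
    assert allele == expected
    assert qpos == 25


def test_snv_low_base_quality_is_uncalled():
    allele, _ = call_allele(snv_read("T", qual_at_site=5), 125, "C", "T", min_baseq=13)
    assert allele == UNCALLED


def test_site_inside_read_deletion_is_uncalled():
    read = make_read(start=100, cigar="20M10D30M", seq="A" * 50)
    allele, _ = call_allele(read, 125, "C", "T")  # pos0 125 falls in the deletion
    assert allele == UNCALLED


def test_insertion_alt_ref_and_other():
    # anchor G at reference position 119 (query index 19)
    seq = "A" * 19 + "G" + "CAT" + "A" * 28
    carrier = make_read(start=100, cigar="20M3I28M", seq=seq)
    assert call_allele(carrier, 119, "G", "GCAT")[0] == ALT

    plain = make_read(start=100, cigar="50M", seq="A" * 19 + "G" + "A" * 30)
    assert call_allele(plain, 119, "G", "GCAT")[0] == REF

    other_ins = make_read(start=100, cigar="20M2I28M", seq="A" * 19 + "G" + "TT" + "A" * 28)
    assert call_allele(other_ins, 119, "G", "GCAT")[0] == OTHER


def test_insertion_read_ending_at_anchor_is_uncalled():
    read = make_read(start=100, cigar="20M", seq="A" * 19 + "G")
    assert call_allele(read, 119, "G", "GCAT")[0] == UNCALLED


def test_deletion_alt_ref_longer_and_partial():
    assert call_allele(make_read(start=100, cigar="20M2D30M", seq="A" * 50), 119, "CAT", "C")[0] == ALT
    assert call_allele(make_read(start=100, cigar="50M", seq="A" * 50), 119, "CAT", "C")[0] == REF
    # deletion extending past the stated span is a different allele
    assert call_allele(make_read(start=100, cigar="20M5D30M", seq="A" * 50), 119, "CAT", "C")[0] == OTHER
    # alignment stopping inside the span cannot resolve the event
    assert call_allele(make_read(start=100, cigar="21M", seq="A" * 21), 119, "CAT", "C")[0] == UNCALLED


def test_mnv_exact_segment_comparison():
    assert call_allele(make_read(start=100, cigar="50M", seq="A" * 25 + "TG" + "A" * 23), 125, "CA", "TG")[0] == ALT
    assert call_allele(make_read(start=100, cigar="50M", seq="A" * 25 + "CA" + "A" * 23), 125, "CA", "TG")[0] == REF
    assert call_allele(make_read(start=100, cigar="50M", seq="A" * 25 + "TT" + "A" * 23), 125, "CA", "TG")[0] == OTHER


# ---------------------------------------------------------------------------
# read-end distances
# ---------------------------------------------------------------------------


def test_end_distances_resolve_orientation():
    fwd = make_read(start=100, cigar="50M", seq="A" * 50)
    assert end_distances(fwd, 3) == (3, 46)
    rev = make_read(start=100, cigar="50M", seq="A" * 50, reverse=True)
    assert end_distances(rev, 3) == (46, 3)  # physical 5' end is the right-hand side


def test_end_distances_exclude_soft_clips():
    read = make_read(start=100, cigar="5S40M5S", seq="A" * 50)
    d5, d3 = end_distances(read, 7)  # query index 7 = aligned index 2
    assert (d5, d3) == (2, 37)
    assert d5 + d3 < read.query_alignment_length


# ---------------------------------------------------------------------------
# amplicon assignment
# ---------------------------------------------------------------------------


def amp(start, end, pid, order=0):
    return AmpliconRecord("chrS", start, end, pid, order=order)


def test_exact_boundary_match_assigns():
    assert assign_to_amplicon(100, 250, [amp(100, 250, "A")], tolerance=2) == "A"


def test_no_candidate_within_tolerance_is_aspecific():
    cands = [amp(100, 250, "A", 0), amp(200, 350, "B", 1)]
    assert assign_to_amplicon(130, 220, cands, tolerance=2) == ASPECIFIC


def test_ties_break_by_design_order():
    cands = [amp(100, 250, "A", 0), amp(102, 252, "B", 1)]
    # span equidistant from both boundary pairs
    assert assign_to_amplicon(101, 251, cands, tolerance=2) == "A"
    cands_swapped = [amp(100, 250, "A", 1), amp(102, 252, "B", 0)]
    assert assign_to_amplicon(101, 251, cands_swapped, tolerance=2) == "B"


@pytest.mark.parametrize("tolerance", [0, 2, 5])
def test_random_assignments_match_exhaustive_rule(tolerance):
    rng = np.random.default_rng(7)
    candidates = []
    for i in range(20):
        start = int(rng.integers(0, 500))
        candidates.append(amp(start, start + int(rng.integers(50, 200)), f"P{i}", order=i))
    for _ in range(200):
        s = int(rng.integers(0, 600))
        e = s + int(rng.integers(40, 220))
        qualifying = [
            (abs(s - c.start) + abs(e - c.end), c.order, c.probe_id)
            for c in candidates
            if abs(s - c.start) <= tolerance and abs(e - c.end) <= tolerance
        ]
        expected = min(qualifying)[2] if qualifying else ASPECIFIC
        assert assign_to_amplicon(s, e, candidates, tolerance) == expected


# ---------------------------------------------------------------------------
# fragment spans
# ---------------------------------------------------------------------------


def test_fragment_span_uses_pair_outer_coordinates():
    left = make_read(start=100, cigar="50M", seq="A" * 50)
    left.flag = 99  # paired, proper, mate reverse, first
    left.template_length = 160
    assert fragment_span(left) == (100, 260)
    right = make_read(start=210, cigar="50M", seq="A" * 50)
    right.flag = 147
    right.template_length = -160
    assert fragment_span(right) == (100, 260)


def test_fragment_span_falls_back_to_read_span():
    single = make_read(start=100, cigar="50M", seq="A" * 50)
    assert fragment_span(single) == (100, 150)
    improper = make_read(start=100, cigar="50M", seq="A" * 50)
    improper.flag = 1  # paired but not proper
    improper.template_length = 300
    assert fragment_span(improper) == (100, 150)


# ---------------------------------------------------------------------------
# collection and aggregation on generated alignments
# ---------------------------------------------------------------------------


def hand_counted_spec():
    """3 covering amplicons; ALT in 2 of them; REF reads in all 3."""
    scenario = fx.Scenario(
        name="hand_counted",
        category="LowAmpFail",  # amp_ca = 2 < 3
        amplicons=((40, 60), (60, 40), (80, 20)),
        tumor_reads=((6, 4), (6, 4), (10, 0)),
    )
    return fx.FixtureSpec(seed=5, mode="germline", scenarios=(scenario,))


@pytest.fixture(scope="module")
def hand_counted(tmp_path_factory):
    root = tmp_path_factory.mktemp("hand_counted")
    spec = hand_counted_spec()
    paths = fx.generate(spec, root)
    index = read_design(paths.design)
    aln = pysam.AlignmentFile(str(paths.bam))
    row = fx.truth_table(spec)[0]
    return aln, index, row


def test_hand_counted_amplicon_evidence(hand_counted):
    aln, index, row = hand_counted
    ev = collect_evidence(aln, row.chrom, row.pos, row.ref, row.alt, index, GERMLINE_CFG)
    assert (ev.amp_c, ev.amp_ca, ev.amp_cr) == (3, 2, 3)
    assert ev.amp_fa == pytest.approx(2 / 3)
    assert (ev.depth, ev.alt_depth, ev.ref_depth) == (30, 8, 22)


def test_every_overlapping_read_yields_one_observation(hand_counted):
    aln, index, row = hand_counted
    obs = collect_observations(aln, row.chrom, row.pos - 1, row.ref, row.alt, index, GERMLINE_CFG)
    assert len(obs) == 30
    per_amplicon = {}
    for o in obs:
        per_amplicon[o.amplicon] = per_amplicon.get(o.amplicon, 0) + 1
    assert sum(per_amplicon.values()) == len(obs)
    assert per_amplicon.get(ASPECIFIC, 0) == 0
    for o in obs:
        assert o.dist_5p >= 0 and o.dist_3p >= 0


def test_no_reads_at_position_gives_empty_evidence(hand_counted):
    aln, index, row = hand_counted
    ev = collect_evidence(aln, row.chrom, row.pos + 500, row.ref, row.alt, index, GERMLINE_CFG)
    assert (ev.depth, ev.amp_ca, ev.amp_cr, ev.amp_fa) == (0, 0, 0, 0)


def test_chromosome_absent_from_alignments_gives_depth_zero(hand_counted):
    aln, index, row = hand_counted
    ev = collect_evidence(aln, "chrMissing", 100, "A", "T", index, GERMLINE_CFG)
    assert ev.depth == 0


def test_alt_only_in_aspecific_fragment_gives_zero_alt_amplicons(tmp_path):
    scenario = fx.Scenario(
        name="fig_style_artefact",
        category="LowAmpFail",
        amplicons=((40, 60), (60, 40), (80, 20)),
        tumor_reads=((10, 0), (10, 0), (10, 0)),
        tumor_aspecific=(0, 5),
    )
    spec = fx.FixtureSpec(seed=5, mode="germline", scenarios=(scenario,))
    paths = fx.generate(spec, tmp_path)
    index = read_design(paths.design)
    aln = pysam.AlignmentFile(str(paths.bam))
    row = fx.truth_table(spec)[0]
    ev = collect_evidence(aln, row.chrom, row.pos, row.ref, row.alt, index, GERMLINE_CFG)
    assert ev.alt_depth == 5
    assert ev.amp_ca == 0
    assert ev.aspecific_reads == 5


def test_pair_outer_span_drives_assignment(tmp_path):
    """Mates shorter than the amplicon are still assigned via the pair span."""
    contig_len = 100000
    sam = tmp_path / "pairs.sam"
    lines = [
        "@HD\tVN:1.6\tSO:unsorted\n",
        f"@SQ\tSN:chrS\tLN:{contig_len}\n",
        # proper pair spanning exactly the amplicon [100, 260)
        f"p1\t99\tchrS\t101\t60\t50M\t=\t211\t160\t{'A' * 50}\t{'I' * 50}\n",
        f"p1\t147\tchrS\t211\t60\t50M\t=\t101\t-160\t{'A' * 50}\t{'I' * 50}\n",
        # unpaired read with the same left span: does not match the amplicon
        f"u1\t0\tchrS\t101\t60\t50M\t*\t0\t0\t{'A' * 50}\t{'I' * 50}\n",
    ]
    sam.write_text("".join(lines))
    bam = tmp_path / "pairs.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    bed = tmp_path / "d.bed"
    bed.write_text("chrS\t100\t260\tAMP\n")
    index = read_design(bed)
    aln = pysam.AlignmentFile(str(bam))
    obs = collect_observations(aln, "chrS", 120, "A", "T", index, GERMLINE_CFG)
    by_name = {o.read_name: o.amplicon for o in obs}
    assert by_name == {"p1": "AMP", "u1": ASPECIFIC}


# ---------------------------------------------------------------------------
# derived fractions
# ---------------------------------------------------------------------------


def ev(depth=0, alt=0, ref=0, end_alt=0, amp_c=0, amp_ca=0, amp_cr=0):
    return AmpliconEvidence(amp_c, amp_ca, amp_cr, depth, alt, ref, end_alt, 0)


@pytest.mark.parametrize(
    "evidence, expected",
    [
        (ev(depth=50, alt=10), 0.0),
        (ev(depth=50, alt=10, end_alt=6), 12.0),
        (ev(depth=20, alt=20, end_alt=20), 100.0),
        (ev(), 0.0),
    ],
)
def test_end_position_alt_fraction(evidence, expected):
    assert end_position_alt_fraction(evidence) == pytest.approx(expected)


@pytest.mark.parametrize(
    "evidence, expected",
    [(ev(depth=100), 0.0), (ev(depth=100, alt=3), 3.0), (ev(depth=100, alt=1), 1.0), (ev(), 0.0)],
)
def test_normal_alt_fraction(evidence, expected):
    assert normal_alt_fraction(evidence) == pytest.approx(expected)


def test_aggregate_ignores_low_mapq_nothing_but_counts_duplicates(tmp_path):
    """Duplicate-flagged reads still contribute; low MAPQ reads do not."""
    contig_len = 100000
    sam = tmp_path / "dups.sam"
    lines = [
        "@HD\tVN:1.6\tSO:unsorted\n",
        f"@SQ\tSN:chrS\tLN:{contig_len}\n",
        f"a\t0\tchrS\t101\t60\t50M\t*\t0\t0\t{'A' * 50}\t{'I' * 50}\n",
        f"b\t1024\tchrS\t101\t60\t50M\t*\t0\t0\t{'A' * 50}\t{'I' * 50}\n",  # duplicate
        f"c\t0\tchrS\t101\t5\t50M\t*\t0\t0\t{'A' * 50}\t{'I' * 50}\n",  # below min_mapq
    ]
    sam.write_text("".join(lines))
    bam = tmp_path / "dups.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    bed = tmp_path / "d.bed"
    bed.write_text("chrS\t100\t150\tAMP\n")
    aln = pysam.AlignmentFile(str(bam))
    ev_out = collect_evidence(aln, "chrS", 121, "A", "T", read_design(bed), GERMLINE_CFG)
    assert ev_out.depth == 2


# ---------------------------------------------------------------------------
# assignment properties (hypothesis)
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=200, derandomize=True)
@given(
    span_start=st.integers(0, 600),
    span_len=st.integers(1, 300),
    tolerance=st.integers(0, 5),
    layout=st.lists(st.tuples(st.integers(0, 600), st.integers(1, 300)), min_size=0, max_size=8),
)
def test_assignment_respects_tolerance_bound(span_start, span_len, tolerance, layout):
    """Whatever the layout, an assigned amplicon is a candidate with both
    boundary offsets within tolerance; ASPECIFIC otherwise."""
    candidates = [amp(s, s + l, f"H{i}", order=i) for i, (s, l) in enumerate(layout)]
    span_end = span_start + span_len
    result = assign_to_amplicon(span_start, span_end, candidates, tolerance)
    qualifying = {
        c.probe_id
        for c in candidates
        if abs(span_start - c.start) <= tolerance and abs(span_end - c.end) <= tolerance
    }
    if qualifying:
        assert result in qualifying
    else:
        assert result == ASPECIFIC
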