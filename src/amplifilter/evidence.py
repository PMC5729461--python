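"""Per-variant read evidence extraction.

For each candidate variant the pipeline walks every alignment overlapping
the site, calls the allele each read carries, assigns the read (or, for a
proper pair, the pair's outer fragment span) to one theoretical amplicon
from the design — or marks it aspecific when its boundaries match no
predicted restriction fragment — and aggregates amplicon-level support
counts.  The central quantity is the fraction of covering theoretical
amplicons that contain the alternative allele: a genuine variant should
be seen in several independently captured fragments, whereas enrichment
artefacts concentrate in aspecific fragments or at read ends.

Coordinates are 0-based throughout this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pysam

from .config import FilterConfig
from .design import AmpliconRecord, DesignIndex

log = logging.getLogger(__name__)

# allele classes for one read at one site
REF = "REF"
ALT = "ALT"
OTHER = "OTHER"
UNCALLED = "UNCALLED"

#: sentinel amplicon assignment for reads matching no covering amplicon
ASPECIFIC = "ASPECIFIC"


@dataclass(frozen=True)
class ReadObservation:
    """One read's contribution at a variant site.

    ``dist_5p``/``dist_3p`` are distances (in aligned-read coordinates,
    0-based) between the variant and the read's physical 5'/3' ends after
    resolving reverse-complement orientation, so 5' always means the
    sequencing start of that read.
    """

    read_name: str
    amplicon: str  # probe_id or ASPECIFIC
    allele: str
    dist_5p: int
    dist_3p: int
    mapq: int


@dataclass(frozen=True)
class AmpliconEvidence:
    """Aggregate amplicon-level support for one (variant, ALT) pair.

    ``amp_c`` counts design amplicons covering the position (whether or
    not they captured reads); ``amp_ca``/``amp_cr`` count those with at
    least one assigned ALT/REF-supporting read.  Depths count reads, with
    duplicates retained as the enrichment chemistry requires.
    """

    amp_c: int
    amp_ca: int
    amp_cr: int
    depth: int
    alt_depth: int
    ref_depth: int
    end_alt_reads: int
    aspecific_reads: int

    def __post_init__(self) -> None:
        assert 0 <= self.amp_ca <= self.amp_c or self.amp_c == 0 and self.amp_ca == 0
        assert 0 <= self.amp_cr <= self.amp_c or self.amp_c == 0 and self.amp_cr == 0
        assert self.alt_depth + self.ref_depth <= self.depth
        assert self.end_alt_reads <= self.alt_depth

    @property
    def amp_fa(self) -> float:
        """ALT amplicon fraction: amp_ca / amp_c, 0 when amp_c = 0."""
        return self.amp_ca / self.amp_c if self.amp_c else 0.0

    @property
    def amp_fr(self) -> float:
        """REF amplicon fraction: amp_cr / amp_c, 0 when amp_c = 0."""
        return self.amp_cr / self.amp_c if self.amp_c else 0.0


EMPTY_EVIDENCE = AmpliconEvidence(0, 0, 0, 0, 0, 0, 0, 0)


def end_position_alt_fraction(evidence: AmpliconEvidence) -> float:
    """Percent of all reads carrying ALT within ``min_read_pos`` bases of a read end."""
    if evidence.depth == 0:
        return 0.0
    return 100.0 * evidence.end_alt_reads / evidence.depth


def normal_alt_fraction(evidence_normal: AmpliconEvidence) -> float:
    """Percent of normal-sample reads carrying the ALT allele."""
    if evidence_normal.depth == 0:
        return 0.0
    return 100.0 * evidence_normal.alt_depth / evidence_normal.depth


# ---------------------------------------------------------------------------
# allele calling
# ---------------------------------------------------------------------------


def _aligned_pairs(read: pysam.AlignedSegment):
    return read.get_aligned_pairs()


def _anchor_query_pos(pairs, pos0: int):
    """Query index aligned to reference pos0, plus the nearest aligned
    query index at or before it (fallback for deleted sites)."""
    nearest = None
    for q, r in pairs:
        if r is None or q is None:
            continue
        if r <= pos0:
            nearest = q
        if r == pos0:
            return q, nearest
        if r > pos0:
            break
    return None, nearest


def call_allele(
    read: pysam.AlignedSegment,
    pos0: int,
    ref: str,
    alt: str,
    min_baseq: int = 13,
) -> tuple[str, int | None]:
    """Classify the allele ``read`` carries at the site ``(pos0, ref, alt)``.

    Returns ``(allele_class, anchor_query_pos)`` where the anchor is the
    query index used for read-end distance measurement (for indels, the
    anchor base of the edit).  SNVs compare the aligned base; insertions
    require the stated inserted sequence immediately after the anchor;
    deletions require exactly the stated reference span to be deleted.
    ``UNCALLED`` covers low base quality and reads that cannot resolve
    the event (site deleted/skipped, alignment ends inside the event).
    """
    ref, alt = ref.upper(), alt.upper()
    pairs = _aligned_pairs(read)
    seq = read.query_sequence or ""
    quals = read.query_qualities

    qpos, nearest = _anchor_query_pos(pairs, pos0)

    if len(ref) == 1 and len(alt) == 1:  # SNV
        if qpos is None:
            return UNCALLED, nearest
        if quals is not None and quals[qpos] < min_baseq:
            return UNCALLED, qpos
        base = seq[qpos].upper()
        if base == alt:
            return ALT, qpos
        if base == ref:
            return REF, qpos
        return OTHER, qpos

    if qpos is None:
        return UNCALLED, nearest
    if quals is not None and quals[qpos] < min_baseq:
        return UNCALLED, qpos

    if len(alt) > len(ref) == 1 and alt[0] == ref[0]:  # simple insertion
        return _call_insertion(pairs, seq, qpos, pos0, alt), qpos
    if len(ref) > len(alt) == 1 and ref[0] == alt[0]:  # simple deletion
        return _call_deletion(read, pairs, pos0, ref), qpos
    return _call_block_substitution(pairs, seq, pos0, ref, alt), qpos


def _call_insertion(pairs, seq: str, anchor_q: int, pos0: int, alt: str) -> str:
    idx = next(i for i, (q, r) in enumerate(pairs) if r == pos0)
    inserted: list[int] = []
    j = idx + 1
    while j < len(pairs) and pairs[j][1] is None:
        if pairs[j][0] is not None:
            inserted.append(pairs[j][0])
        j += 1
    ins_seq = "".join(seq[q] for q in inserted).upper()
    if ins_seq == alt[1:]:
        return ALT
    if not inserted:
        if j >= len(pairs):
            return UNCALLED  # read ends at the anchor: cannot exclude an insertion
        return REF if seq[anchor_q].upper() == alt[0] else OTHER
    return OTHER


def _call_deletion(read: pysam.AlignedSegment, pairs, pos0: int, ref: str) -> str:
    span = range(pos0 + 1, pos0 + len(ref))
    rmap = {r: q for q, r in pairs if r is not None}
    if any(r not in rmap for r in span):
        return UNCALLED  # alignment does not span the putative deletion
    deleted = [r for r in span if rmap[r] is None]
    if not deleted:
        return REF
    if len(deleted) == len(span):
        nxt = pos0 + len(ref)
        if read.reference_end is not None and read.reference_end > nxt and rmap.get(nxt, 0) is None:
            return OTHER  # deletion extends past the stated span
        return ALT
    return OTHER


def _call_block_substitution(pairs, seq: str, pos0: int, ref: str, alt: str) -> str:
    """MNVs / complex alleles: exact aligned-segment comparison over the REF span."""
    rmap = {r: q for q, r in pairs if r is not None}
    span = range(pos0, pos0 + len(ref))
    if any(r not in rmap for r in span):
        return UNCALLED
    qs = [rmap[r] for r in span]
    if any(q is None for q in qs):
        return OTHER
    aligned = "".join(seq[q] for q in qs).upper()
    contiguous = all(b - a == 1 for a, b in zip(qs, qs[1:]))
    if aligned == alt and len(alt) == len(ref) and contiguous:
        return ALT
    if aligned == ref and contiguous:
        return REF
    return OTHER


# ---------------------------------------------------------------------------
# read-end distances and amplicon assignment
# ---------------------------------------------------------------------------


def end_distances(read: pysam.AlignedSegment, qpos: int) -> tuple[int, int]:
    """(dist_5p, dist_3p) of query index ``qpos`` within the aligned portion,
    orientation-resolved so 5' is the sequencing start of the read."""
    start = read.query_alignment_start
    length = read.query_alignment_length
    qa = min(max(qpos - start, 0), length - 1)
    if read.is_reverse:
        return length - 1 - qa, qa
    return qa, length - 1 - qa


def assign_to_amplicon(
    span_start: int,
    span_end: int,
    candidates: Sequence[AmpliconRecord],
    tolerance: int,
) -> str:
    """Assign a fragment span to the best-matching covering amplicon.

    The winner minimizes ``|span_start - start| + |span_end - end|``
    subject to both boundary offsets being within ``tolerance`` bases;
    ties break by design-file order.  Returns :data:`ASPECIFIC` when no
    candidate qualifies.
    """
    best: AmpliconRecord | None = None
    best_score = None
    for cand in sorted(candidates, key=lambda r: r.order):
        d_start = abs(span_start - cand.start)
        d_end = abs(span_end - cand.end)
        if d_start > tolerance or d_end > tolerance:
            continue
        score = d_start + d_end
        if best_score is None or score < best_score:
            best, best_score = cand, score
    return best.probe_id if best is not None else ASPECIFIC


def fragment_span(read: pysam.AlignedSegment) -> tuple[int, int]:
    """Outer fragment span used for amplicon assignment.

    Properly paired reads use the pair's outer coordinates (recovered
    from TLEN so the mate need not be fetched); everything else falls
    back to the single read's aligned span.
    """
    if read.is_paired and read.is_proper_pair and read.template_length:
        tlen = read.template_length
        if tlen > 0:
            return read.reference_start, read.reference_start + tlen
        return read.reference_end + tlen, read.reference_end
    return read.reference_start, read.reference_end


# ---------------------------------------------------------------------------
# evidence collection
# ---------------------------------------------------------------------------


def collect_observations(
    alignments: pysam.AlignmentFile,
    chrom: str,
    pos0: int,
    ref: str,
    alt: str,
    index: DesignIndex,
    config: FilterConfig,
) -> list[ReadObservation]:
    """One :class:`ReadObservation` per quality-passing read overlapping ``pos0``.

    Unmapped, secondary, supplementary and QC-fail records are excluded;
    duplicates are retained.  A chromosome absent from the alignment file
    yields an empty list.
    """
    candidates = index.covering_ordered(chrom, pos0)
    try:
        fetched = alignments.fetch(chrom, pos0, pos0 + 1)
    except ValueError:
        log.warning("chromosome %r absent from %s; treating depth as 0", chrom, alignments.filename)
        return []
    observations: list[ReadObservation] = []
    for read in fetched:
        if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_qcfail:
            continue
        if read.mapping_quality < config.min_mapq:
            continue
        if read.reference_start > pos0 or (read.reference_end or read.reference_start) <= pos0:
            continue
        allele, qpos = call_allele(read, pos0, ref, alt, min_baseq=config.min_baseq)
        if qpos is None:
            qpos = read.query_alignment_start
        d5, d3 = end_distances(read, qpos)
        span_start, span_end = fragment_span(read)
        amplicon = assign_to_amplicon(span_start, span_end, candidates, config.assignment_tolerance)
        observations.append(
            ReadObservation(
                read_name=read.query_name,
                amplicon=amplicon,
                allele=allele,
                dist_5p=d5,
                dist_3p=d3,
                mapq=read.mapping_quality,
            )
        )
    return observations


def aggregate(observations: Sequence[ReadObservation], amp_c: int, config: FilterConfig) -> AmpliconEvidence:
    """Fold per-read observations into :class:`AmpliconEvidence`."""
    alt_amps: set[str] = set()
    ref_amps: set[str] = set()
    depth = alt_depth = ref_depth = end_alt = aspecific = 0
    for obs in observations:
        if obs.amplicon == ASPECIFIC:
            aspecific += 1
        if obs.allele == UNCALLED:
            continue
        depth += 1
        if obs.allele == ALT:
            alt_depth += 1
            if obs.dist_5p < config.min_read_pos or obs.dist_3p < config.min_read_pos:
                end_alt += 1
            if obs.amplicon != ASPECIFIC:
                alt_amps.add(obs.amplicon)
        elif obs.allele == REF:
            ref_depth += 1
            if obs.amplicon != ASPECIFIC:
                ref_amps.add(obs.amplicon)
    return AmpliconEvidence(
        amp_c=amp_c,
        amp_ca=len(alt_amps),
        amp_cr=len(ref_amps),
        depth=depth,
        alt_depth=alt_depth,
        ref_depth=ref_depth,
        end_alt_reads=end_alt,
        aspecific_reads=aspecific,
    )


def collect_evidence(
    alignments: pysam.AlignmentFile,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    index: DesignIndex,
    config: FilterConfig,
) -> AmpliconEvidence:
    """Amplicon-level evidence for one ALT allele at a 1-based VCF position."""
    pos0 = pos - 1
    observations = collect_observations(alignments, chrom, pos0, ref, alt, index, config)
    amp_c = len(index.covering(chrom, pos0))
    return aggregate(observations, amp_c, config)
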