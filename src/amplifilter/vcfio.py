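"""VCF reading, annotation and VCF v4.1 output.

Input records are parsed with pysam; for output every record is
re-serialized from its columns so that the FILTER replacement, the
fixed-precision amplicon metrics and the header block are byte-stable
across runs and thread counts.  Variants are flagged, never removed: the
assigned category replaces FILTER (the original value is preserved under
the INFO key ``OrigFilter``) and the amplicon metrics are appended to
INFO under the keys AmpFR, AmpFA, AmpCR, AmpCA, AmpC, AmpF_OA and
AmpF_OR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .engine import (
    AMP_PASS,
    CATEGORIES,
    DEPTH_FAIL,
    DEPTH_FAIL_NORMAL,
    DEPTH_FAIL_TUMOR,
    LOW_AMP_FAIL,
    MATCH_AMP_PASS,
    NORMAL_FAIL,
    ONE_AMP_PASS,
    POSITION_FAIL,
    FilterVerdict,
    most_severe,
)
from .errors import VcfParseError

log = logging.getLogger(__name__)

#: INFO keys added to every classified record, in output order.
#: Descriptions for the seven metric keys are the published field notes.
INFO_FIELDS = (
    ("AmpFR", "A", "Float", "Amplicon fraction for reference allele"),
    ("AmpFA", "A", "Float", "Amplicon fraction for alternative allele"),
    ("AmpCR", "A", "Integer", "Amplicon count for reference allele"),
    ("AmpCA", "A", "Integer", "Amplicon count for alternative allele"),
    ("AmpC", "1", "Integer", "Amplicon total count"),
    ("AmpF_OA", "A", "Float", "Amplicon count offset compared to allelic depth, for alternative allele"),
    ("AmpF_OR", "A", "Float", "Amplicon count offset compared to allelic depth, for reference allele"),
)

AUX_INFO_FIELDS = (
    ("OrigFilter", "1", "String", "FILTER value assigned by the upstream caller before amplicon filtering"),
    ("AmpCat", "A", "String", "Per-ALT-allele amplicon filter category"),
)

FILTER_DESCRIPTIONS = {
    DEPTH_FAIL: "Insufficient read depth at the variant position",
    DEPTH_FAIL_TUMOR: "Insufficient read depth in the tumor sample",
    DEPTH_FAIL_NORMAL: "Insufficient read depth in the normal sample",
    ONE_AMP_PASS: "Variant covered by and present in a single theoretical amplicon",
    LOW_AMP_FAIL: "Variant supported by too few of the covering theoretical amplicons",
    MATCH_AMP_PASS: "Variant covered by two theoretical amplicons and present in both",
    POSITION_FAIL: "Alternative allele concentrated at read ends",
    NORMAL_FAIL: "Alternative allele present above threshold in the paired normal sample",
    AMP_PASS: "Variant passed all amplicon-based filters",
}

_ADDED_KEYS = tuple(f[0] for f in INFO_FIELDS) + tuple(f[0] for f in AUX_INFO_FIELDS)


@dataclass
class VariantSite:
    """One VCF record, kept both parsed and as its raw columns."""

    chrom: str
    pos: int  # 1-based
    vid: str
    ref: str
    alts: tuple[str, ...]
    qual: str
    filter_: str
    cols: list[str]

    @property
    def is_symbolic(self) -> bool:
        """True when any ALT is symbolic/structural (``<DEL>``, breakends, ``*``)."""
        return any(("<" in a) or ("[" in a) or ("]" in a) or a in (".", "*") for a in self.alts)


def _site_from_record(rec: pysam.VariantRecord) -> VariantSite:
    cols = str(rec).rstrip("\n").split("\t")
    return VariantSite(
        chrom=cols[0],
        pos=int(cols[1]),
        vid=cols[2],
        ref=cols[3],
        alts=tuple(cols[4].split(",")),
        qual=cols[5],
        filter_=cols[6],
        cols=cols,
    )


def read_vcf(path: str | Path) -> tuple[str, list[VariantSite]]:
    """Parse a VCF (plain or gzip) into its header text and record list."""
    path = Path(path)
    if not path.exists():
        raise VcfParseError(f"variant file not found: {path}")
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: not a parseable VCF: {exc}") from None
    header = str(vf.header)
    if "#CHROM" not in header:
        raise VcfParseError(f"{path}: missing #CHROM header line")
    sites = [_site_from_record(rec) for rec in vf]
    vf.close()
    return header, sites


def _fmt_fraction(value: float) -> str:
    return f"{value:.4f}"


def annotate(site: VariantSite, verdicts: Sequence[FilterVerdict]) -> VariantSite:
    """Return a copy of ``site`` with FILTER replaced by the (most severe)
    category and the amplicon metrics appended to INFO.

    ``verdicts`` is ordered like ``site.alts`` (one per ALT allele).
    """
    if len(verdicts) != len(site.alts):
        raise ValueError("one verdict per ALT allele is required")
    categories = [v.category for v in verdicts]
    evs = [v.evidence_tumor for v in verdicts]
    amp_c = evs[0].amp_c

    pairs: list[tuple[str, str]] = [
        ("AmpFR", ",".join(_fmt_fraction(e.amp_fr) for e in evs)),
        ("AmpFA", ",".join(_fmt_fraction(e.amp_fa) for e in evs)),
        ("AmpCR", ",".join(str(e.amp_cr) for e in evs)),
        ("AmpCA", ",".join(str(e.amp_ca) for e in evs)),
        ("AmpC", str(amp_c)),
        ("AmpF_OA", ",".join(_fmt_fraction(v.amp_f_oa) for v in verdicts)),
        ("AmpF_OR", ",".join(_fmt_fraction(v.amp_f_or) for v in verdicts)),
    ]
    if site.filter_ != ".":
        pairs.append(("OrigFilter", site.filter_.replace(";", ",")))
    if len(site.alts) > 1:
        pairs.append(("AmpCat", ",".join(categories)))

    old_info = site.cols[7]
    kept: list[str] = []
    if old_info not in (".", ""):
        for item in old_info.split(";"):
            key = item.split("=", 1)[0]
            if key in _ADDED_KEYS:
                log.warning("INFO key %s already present at %s:%d; replaced", key, site.chrom, site.pos)
                continue
            kept.append(item)
    new_info = ";".join(kept + [f"{k}={v}" for k, v in pairs])

    cols = list(site.cols)
    cols[6] = most_severe(categories)
    cols[7] = new_info
    return VariantSite(site.chrom, site.pos, site.vid, site.ref, site.alts, site.qual, cols[6], cols)


def build_header(original_header: str) -> str:
    """VCF v4.1 output header: original lines, minus any clashing FILTER/INFO
    declarations, plus this pipeline's nine FILTER and nine INFO lines."""
    our_filter_ids = set(CATEGORIES)
    our_info_ids = set(_ADDED_KEYS)
    kept: list[str] = []
    chrom_line = None
    for line in original_header.rstrip("\n").split("\n"):
        if line.startswith("##fileformat="):
            continue
        if line.startswith("#CHROM"):
            chrom_line = line
            continue
        for prefix, ids in (("##FILTER=<ID=", our_filter_ids), ("##INFO=<ID=", our_info_ids)):
            if line.startswith(prefix) and line[len(prefix):].split(",", 1)[0] in ids:
                break
        else:
            kept.append(line)
    if chrom_line is None:
        raise VcfParseError("input header lacks a #CHROM line")
    lines = ["##fileformat=VCFv4.1"]
    lines.extend(kept)
    for cat in CATEGORIES:
        lines.append(f'##FILTER=<ID={cat},Description="{FILTER_DESCRIPTIONS[cat]}">')
    for key, number, vtype, desc in INFO_FIELDS + AUX_INFO_FIELDS:
        lines.append(f'##INFO=<ID={key},Number={number},Type={vtype},Description="{desc}">')
    lines.append(chrom_line)
    return "\n".join(lines) + "\n"


def write_vcf(out_path: str | Path, original_header: str, sites: Iterable[VariantSite]) -> Path:
    """Write the annotated (or passed-through) records to ``out_path``.

    Record order is the caller's; output is deterministic (no timestamps).
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    header = build_header(original_header)
    with open(out_path, "w") as fh:
        fh.write(header)
        for site in sites:
            fh.write("\t".join(site.cols))
            fh.write("\n")
    return out_path
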