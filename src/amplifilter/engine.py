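"""The ordered seven-category decision tree.

Every (variant, ALT allele) pair is assigned to exactly one quality
category by evaluating the rules below in a fixed order and stopping at
the first match:

1. depth floor — too few reads in the sample (germline: ``DepthFail``;
   somatic: ``DepthFailTumor`` then ``DepthFailNormal``);
2. single covering amplicon that contains the variant → ``OneAmpPass``
   (a panel-design limitation; no further filtering);
3. too few variant-containing amplicons → ``LowAmpFail`` (with >2
   covering amplicons, fewer than 3 must not support ALT; with exactly 2,
   support from at most 1; zero covering amplicons means the site is off
   the design and is likewise failed);
4. exactly 2 covering amplicons, both supporting → ``MatchAmpPass``
   (limited discriminative power; terminal);
5. ALT concentrated at physical read ends (> ``min_read_pos_fraction`` %
   of all reads) → ``PositionFail``;
6. somatic only: ALT in > ``min_frac`` % of normal-sample reads →
   ``NormalFail``;
7. everything passed → ``AmpPass``.

Threshold comparisons at steps 5 and 6 are strict: a fraction exactly at
the cut-off does not fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import GERMLINE, SOMATIC, FilterConfig
from .errors import ConfigError
from .evidence import AmpliconEvidence, end_position_alt_fraction, normal_alt_fraction

log = logging.getLogger(__name__)

DEPTH_FAIL = "DepthFail"
DEPTH_FAIL_TUMOR = "DepthFailTumor"
DEPTH_FAIL_NORMAL = "DepthFailNormal"
ONE_AMP_PASS = "OneAmpPass"
LOW_AMP_FAIL = "LowAmpFail"
MATCH_AMP_PASS = "MatchAmpPass"
POSITION_FAIL = "PositionFail"
NORMAL_FAIL = "NormalFail"
AMP_PASS = "AmpPass"

#: the nine FILTER labels the pipeline can emit
CATEGORIES = (
    DEPTH_FAIL,
    DEPTH_FAIL_TUMOR,
    DEPTH_FAIL_NORMAL,
    ONE_AMP_PASS,
    LOW_AMP_FAIL,
    MATCH_AMP_PASS,
    POSITION_FAIL,
    NORMAL_FAIL,
    AMP_PASS,
)

PASSING_CATEGORIES = frozenset({AMP_PASS, ONE_AMP_PASS, MATCH_AMP_PASS})

#: most-severe-first ordering used to pick a record-level FILTER for
#: multi-allelic records
SEVERITY = (
    DEPTH_FAIL,
    DEPTH_FAIL_TUMOR,
    DEPTH_FAIL_NORMAL,
    LOW_AMP_FAIL,
    POSITION_FAIL,
    NORMAL_FAIL,
    ONE_AMP_PASS,
    MATCH_AMP_PASS,
    AMP_PASS,
)


def most_severe(categories) -> str:
    return min(categories, key=SEVERITY.index)


@dataclass(frozen=True)
class FilterVerdict:
    """Classification outcome for one ALT allele, plus serializable metrics."""

    category: str
    evidence_tumor: AmpliconEvidence
    evidence_normal: AmpliconEvidence | None
    amp_f_oa: float
    amp_f_or: float


def compute_offsets(evidence: AmpliconEvidence) -> tuple[float, float]:
    """Amplicon-fraction offsets against allelic depth.

    ``amp_f_oa = AmpFA - alt_depth/depth`` and ``amp_f_or = AmpFR -
    ref_depth/depth``: a large positive/negative offset flags
    disagreement between amplicon-level and read-level support.  Both are
    0 for degenerate evidence (no depth or no covering amplicon).
    """
    if evidence.depth == 0 or evidence.amp_c == 0:
        return 0.0, 0.0
    amp_f_oa = evidence.amp_fa - evidence.alt_depth / evidence.depth
    amp_f_or = evidence.amp_fr - evidence.ref_depth / evidence.depth
    return amp_f_oa, amp_f_or


def classify(
    evidence: AmpliconEvidence,
    evidence_normal: AmpliconEvidence | None,
    config: FilterConfig,
) -> FilterVerdict:
    """Apply the ordered decision tree to one allele's evidence.

    ``evidence`` is the tumor sample in somatic mode, the single sample
    in germline mode; ``evidence_normal`` must be present iff somatic.
    """
    somatic = config.mode == SOMATIC
    if somatic and evidence_normal is None:
        raise ConfigError("somatic classification requires normal-sample evidence")
    if not somatic and evidence_normal is not None:
        raise ConfigError("germline classification must not receive normal-sample evidence")

    category = _decide(evidence, evidence_normal, config, somatic)
    amp_f_oa, amp_f_or = compute_offsets(evidence)
    return FilterVerdict(category, evidence, evidence_normal, amp_f_oa, amp_f_or)


def _decide(
    ev: AmpliconEvidence,
    ev_n: AmpliconEvidence | None,
    config: FilterConfig,
    somatic: bool,
) -> str:
    # (1) depth floor
    if somatic:
        if ev.depth < config.min_depth_tumor:
            return DEPTH_FAIL_TUMOR
        if ev_n.depth < config.min_depth_normal:
            return DEPTH_FAIL_NORMAL
    else:
        if ev.depth < config.min_depth:
            return DEPTH_FAIL

    c, a = ev.amp_c, ev.amp_ca
    # (2) single-amplicon design limitation
    if c == 1 and a == 1:
        return ONE_AMP_PASS
    # (3) insufficient amplicon-level support
    if c == 0:
        log.warning("variant position not covered by any design amplicon (off-design)")
        return LOW_AMP_FAIL
    if c == 1:  # a == 0: no genuine amplicon contains the variant
        return LOW_AMP_FAIL
    if c == 2 and a <= 1:
        return LOW_AMP_FAIL
    if c > 2 and a < 3:
        return LOW_AMP_FAIL
    # (4) two covering amplicons, both supporting (terminal)
    if c == 2 and a == 2:
        return MATCH_AMP_PASS
    # (5) positional bias at physical read ends
    if end_position_alt_fraction(ev) > config.min_read_pos_fraction:
        return POSITION_FAIL
    # (6) contamination of the paired normal
    if somatic and normal_alt_fraction(ev_n) > config.min_frac:
        return NORMAL_FAIL
    # (7) all criteria passed
    return AMP_PASS
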