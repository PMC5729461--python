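"""Amplicon design file handling.

Haloplex-style enrichment designs list every theoretical restriction
fragment (amplicon) the assay is expected to produce, as a BED interval
with a probe identifier.  Fragment boundaries are reproducible because
they are set by restriction sites, so during filtering the design is the
reference against which observed read spans are judged genuine or
aspecific.  The only query the pipeline needs is "which theoretical
amplicons cover genomic position p"; :class:`DesignIndex` answers it with
a per-chromosome interval tree.

Coordinates follow the BED standard: 0-based, half-open ``[start, end)``.
VCF positions must be converted to 0-based before querying.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from .errors import DesignParseError

log = logging.getLogger(__name__)

_SKIP_PREFIXES = ("track", "browser", "#")


@dataclass(frozen=True)
class AmpliconRecord:
    """One theoretical amplicon (restriction fragment) from the design.

    ``order`` is the record's rank in the design file; it breaks ties
    during read-to-amplicon assignment and does not participate in
    equality or hashing.
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    probe_id: str
    order: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DesignParseError(
                f"amplicon {self.probe_id!r}: start {self.start} must be < end {self.end}"
            )
        if not self.probe_id:
            raise DesignParseError(f"amplicon at {self.chrom}:{self.start}-{self.end} has an empty probe id")

    @property
    def length(self) -> int:
        return self.end - self.start


class DesignIndex:
    """Positional lookup over a loaded amplicon design."""

    def __init__(self, records: Iterable[AmpliconRecord]):
        self._records: tuple[AmpliconRecord, ...] = tuple(records)
        seen: set[tuple[str, int, int, str]] = set()
        self._trees: dict[str, IntervalTree] = {}
        for rec in self._records:
            key = (rec.chrom, rec.start, rec.end, rec.probe_id)
            if key in seen:
                raise DesignParseError(f"duplicate design record {key}")
            seen.add(key)
            self._trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec)
        self._warned_chroms: set[str] = set()

    @property
    def total(self) -> int:
        return len(self._records)

    @property
    def records(self) -> tuple[AmpliconRecord, ...]:
        return self._records

    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def covering(self, chrom: str, pos: int) -> set[AmpliconRecord]:
        """Amplicons whose half-open interval contains 0-based ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            if chrom not in self._warned_chroms:
                self._warned_chroms.add(chrom)
                log.warning("chromosome %r is absent from the amplicon design", chrom)
            return set()
        return {iv.data for iv in tree.at(pos)}

    def covering_ordered(self, chrom: str, pos: int) -> list[AmpliconRecord]:
        """Same as :meth:`covering`, sorted by design-file order."""
        return sorted(self.covering(chrom, pos), key=lambda r: r.order)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_data_lines(path: Path) -> Iterator[tuple[int, str]]:
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def read_design(path: str | Path) -> DesignIndex:
    """Parse a 4+-column amplicon-design BED into a :class:`DesignIndex`.

    Columns beyond the fourth (score, strand, ...) are ignored.  Header
    lines starting with ``track``, ``browser`` or ``#`` are skipped.
    Raises :class:`DesignParseError` naming the offending line for
    malformed coordinates, short lines or duplicate records.
    """
    path = Path(path)
    if not path.exists():
        raise DesignParseError(f"design file not found: {path}")
    records: list[AmpliconRecord] = []
    for lineno, line in _iter_data_lines(path):
        cols = line.split("\t")
        if len(cols) < 4:
            raise DesignParseError(f"{path}:{lineno}: expected >=4 tab-separated columns, got {len(cols)}")
        chrom, start_s, end_s, probe_id = cols[0], cols[1], cols[2], cols[3]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise DesignParseError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
        try:
            rec = AmpliconRecord(chrom, start, end, probe_id, order=len(records))
        except DesignParseError as exc:
            raise DesignParseError(f"{path}:{lineno}: {exc}") from None
        records.append(rec)
    try:
        index = DesignIndex(records)
    except DesignParseError as exc:
        raise DesignParseError(f"{path}: {exc}") from None
    log.info("loaded %d amplicons from %s", index.total, path)
    return index


def amplicons_covering(index: DesignIndex, chrom: str, pos: int) -> set[AmpliconRecord]:
    """Functional form of :meth:`DesignIndex.covering`."""
    return index.covering(chrom, pos)
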