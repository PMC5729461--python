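"""End-to-end orchestration: VCF in, classified VCF v4.1 out.

Each variant's verdict depends only on its own read evidence, so the
record list is partitioned into contiguous blocks, classified
independently (optionally in worker processes) and reassembled in input
order.  Output is byte-identical for any thread count.
"""

from __future__ import annotations

import logging
import multiprocessing
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .config import GERMLINE, SOMATIC, FilterConfig, load_config
from .design import DesignIndex, read_design
from .engine import PASSING_CATEGORIES, FilterVerdict, classify
from .errors import AmplifilterError, ConfigError
from .evidence import collect_evidence
from .vcfio import VariantSite, annotate, read_vcf, write_vcf

log = logging.getLogger(__name__)

SKIPPED = "symbolic_skipped"
OUTPUT_SUFFIX = ".amplifilter.vcf"
PASS_ONLY_SUFFIX = ".amplifilter.pass.vcf"


@dataclass
class RunManifest:
    """Validated description of one filtering run."""

    mode: str
    vcf: Path
    design: Path
    out_dir: Path
    bam: Path | None = None  # germline
    bam_tumor: Path | None = None
    bam_normal: Path | None = None
    config_path: Path | None = None
    threads: int = 1
    pass_only: bool = False

    def __post_init__(self) -> None:
        self.vcf = Path(self.vcf)
        self.design = Path(self.design)
        self.out_dir = Path(self.out_dir)
        if self.mode not in (GERMLINE, SOMATIC):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.threads < 1:
            raise ConfigError("thread count must be >= 1")
        if self.mode == SOMATIC:
            if self.bam_tumor is None or self.bam_normal is None:
                raise ConfigError("somatic mode requires both a tumor and a normal alignment file")
            if self.bam is not None:
                raise ConfigError("somatic mode does not accept a single-sample alignment file")
        else:
            if self.bam is None:
                raise ConfigError("germline mode requires exactly one alignment file")
            if self.bam_tumor is not None or self.bam_normal is not None:
                raise ConfigError("germline mode does not accept tumor/normal alignment files")
        for p in (self.vcf, self.design, self.bam, self.bam_tumor, self.bam_normal, self.config_path):
            if p is not None and not Path(p).exists():
                raise AmplifilterError(f"input path does not exist: {p}")

    @property
    def alignment_paths(self) -> tuple[Path, Path | None]:
        """(primary/tumor, normal-or-None)."""
        if self.mode == SOMATIC:
            return Path(self.bam_tumor), Path(self.bam_normal)
        return Path(self.bam), None


@dataclass
class RunResult:
    output_vcf: Path
    pass_only_vcf: Path | None
    counts: Counter = field(default_factory=Counter)
    n_records: int = 0


def _open_alignments(path: Path) -> pysam.AlignmentFile:
    aln = pysam.AlignmentFile(str(path))
    if not aln.has_index():
        raise AmplifilterError(f"alignment file {path} has no index (.bai/.crai); sort and index it first")
    return aln


def _classify_site(
    site: VariantSite,
    primary: pysam.AlignmentFile,
    normal: pysam.AlignmentFile | None,
    index: DesignIndex,
    config: FilterConfig,
) -> list[FilterVerdict] | None:
    """Verdicts for every ALT allele, or None for symbolic/structural records."""
    if site.is_symbolic:
        log.info("skipping symbolic/structural ALT at %s:%d (%s)", site.chrom, site.pos, ",".join(site.alts))
        return None
    verdicts = []
    for alt in site.alts:
        ev = collect_evidence(primary, site.chrom, site.pos, site.ref, alt, index, config)
        ev_n = None
        if normal is not None:
            ev_n = collect_evidence(normal, site.chrom, site.pos, site.ref, alt, index, config)
        verdicts.append(classify(ev, ev_n, config))
    return verdicts


# -- worker-process machinery -------------------------------------------------

_WORKER: dict = {}


def _worker_init(primary_path: str, normal_path: str | None, design_path: str, config: FilterConfig) -> None:
    _WORKER["primary"] = _open_alignments(Path(primary_path))
    _WORKER["normal"] = _open_alignments(Path(normal_path)) if normal_path else None
    _WORKER["index"] = read_design(design_path)
    _WORKER["config"] = config


def _worker_chunk(args: tuple[int, list[VariantSite]]) -> list[tuple[int, list[FilterVerdict] | None]]:
    start, sites = args
    out = []
    for offset, site in enumerate(sites):
        try:
            out.append((start + offset, _classify_site(site, _WORKER["primary"], _WORKER["normal"], _WORKER["index"], _WORKER["config"])))
        except Exception as exc:
            raise AmplifilterError(f"classification failed at {site.chrom}:{site.pos}: {exc}") from exc
    return out


def _chunks(sites: list[VariantSite], n_chunks: int):
    n = len(sites)
    size = max(1, -(-n // n_chunks))
    for start in range(0, n, size):
        yield start, sites[start : start + size]


def run(manifest: RunManifest) -> RunResult:
    """Execute one filtering run and write the annotated VCF."""
    manifest.out_dir.mkdir(parents=True, exist_ok=True)
    config = load_config(manifest.config_path, manifest.mode)
    log.info("resolved configuration: %s", config.describe())

    header, sites = read_vcf(manifest.vcf)
    log.info("read %d variant records from %s", len(sites), manifest.vcf)

    primary_path, normal_path = manifest.alignment_paths

    results: list[list[FilterVerdict] | None] = [None] * len(sites)
    if manifest.threads > 1 and len(sites) > 1:
        ctx = multiprocessing.get_context("fork")
        with ctx.Pool(
            processes=manifest.threads,
            initializer=_worker_init,
            initargs=(str(primary_path), str(normal_path) if normal_path else None, str(manifest.design), config),
        ) as pool:
            for block in pool.imap_unordered(_worker_chunk, _chunks(sites, manifest.threads * 4)):
                for idx, verdicts in block:
                    results[idx] = verdicts
    else:
        index = read_design(manifest.design)
        primary = _open_alignments(primary_path)
        normal = _open_alignments(normal_path) if normal_path else None
        for idx, site in enumerate(sites):
            try:
                results[idx] = _classify_site(site, primary, normal, index, config)
            except AmplifilterError:
                raise
            except Exception as exc:
                raise AmplifilterError(f"classification failed at {site.chrom}:{site.pos}: {exc}") from exc
            if (idx + 1) % 1000 == 0:
                log.info("processed %d / %d variants", idx + 1, len(sites))
        primary.close()
        if normal is not None:
            normal.close()

    counts: Counter = Counter()
    annotated: list[VariantSite] = []
    for site, verdicts in zip(sites, results):
        if verdicts is None and site.is_symbolic:
            counts[SKIPPED] += 1
            annotated.append(site)  # passed through untouched
            continue
        new_site = annotate(site, verdicts)
        counts[new_site.filter_] += 1
        annotated.append(new_site)

    stem = manifest.vcf.name
    for ext in (".vcf.gz", ".vcf"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    out_path = manifest.out_dir / (stem + OUTPUT_SUFFIX)
    write_vcf(out_path, header, annotated)

    pass_path = None
    if manifest.pass_only:
        pass_path = manifest.out_dir / (stem + PASS_ONLY_SUFFIX)
        write_vcf(pass_path, header, [s for s in annotated if s.filter_ in PASSING_CATEGORIES])

    for label in sorted(counts):
        log.info("category %-16s %6d", label, counts[label])
    log.info("wrote %s (%d records)", out_path, len(annotated))
    return RunResult(output_vcf=out_path, pass_only_vcf=pass_path, counts=counts, n_records=len(annotated))
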