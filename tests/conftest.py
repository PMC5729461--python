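import logging
from pathlib import Path

import pysam
import pytest

from amplifilter import fixtures as fx
from amplifilter.pipeline import RunManifest, run

logging.getLogger().setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def canonical_somatic(tmp_path_factory):
    """Generated canonical somatic fixture plus a completed pipeline run."""
    root = tmp_path_factory.mktemp("canonical_somatic")
    paths = fx.generate(fx.canonical_somatic_spec(), root)
    result = run(
        RunManifest(
            mode="somatic",
            vcf=paths.vcf,
            design=paths.design,
            out_dir=root / "out",
            bam_tumor=paths.bam,
            bam_normal=paths.bam_normal,
        )
    )
    return paths, result


@pytest.fixture(scope="session")
def canonical_germline(tmp_path_factory):
    root = tmp_path_factory.mktemp("canonical_germline")
    paths = fx.generate(fx.canonical_germline_spec(), root)
    result = run(
        RunManifest(mode="germline", vcf=paths.vcf, design=paths.design, out_dir=root / "out", bam=paths.bam)
    )
    return paths, result


def read_truth(paths: fx.FixturePaths):
    import csv

    with open(paths.truth) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def output_records(vcf_path: Path):
    """Data lines of a VCF as column lists."""
    with open(vcf_path) as fh:
        return [line.rstrip("\n").split("\t") for line in fh if not line.startswith("#")]


def info_dict(cols):
    return dict(item.split("=", 1) for item in cols[7].split(";") if "=" in item)


def make_read(
    name="r1",
    chrom_id=0,
    start=100,
    cigar="50M",
    seq=None,
    quals=None,
    mapq=60,
    reverse=False,
    length=50,
    **kwargs,
):
    """An in-memory aligned read against a toy single-contig header."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrS", "LN": 100000}]}
    )
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.reference_id = chrom_id
    read.reference_start = start
    read.cigarstring = cigar
    if seq is None:
        seq = "A" * read.infer_query_length()
    read.query_sequence = seq
    read.query_qualities = pysam.qualitystring_to_array("I" * len(seq)) if quals is None else quals
    read.mapping_quality = mapq
    read.flag = 16 if reverse else 0
    for key, value in kwargs.items():
        setattr(read, key, value)
    return read
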