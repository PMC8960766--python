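"""Shared fixtures: hand-built toy transcripts and small synthetic studies."""

import pysam
import pytest

from ctsplice import synthetic_data as sd
from ctsplice.annotation import build_transcript_model


@pytest.fixture
def toy_tx_plus():
    """Two-exon plus-strand transcript: exons [100,200) and [300,400)."""
    return build_transcript_model(
        "gA", "gA.t1", "chr1", "+", [(100, 200), (300, 400)]
    )


@pytest.fixture
def toy_tx_minus():
    """Mirror of toy_tx_plus on the minus strand."""
    return build_transcript_model(
        "gB", "gB.t1", "chr1", "-", [(100, 200), (300, 400)]
    )


@pytest.fixture(scope="session")
def small_study():
    """40-gene synthetic study with polyA decay: annotation + one sample."""
    scenario = sd.SyntheticScenario(n_genes=40, seed=11, polya_decay=0.3)
    ann = sd.simulate_annotation(scenario)
    counts = sd.simulate_counts(scenario, ann)
    return scenario, ann, counts


@pytest.fixture(scope="session")
def read_level_study(tmp_path_factory):
    """Small read-level study: annotation, counts, and a realising SAM."""
    scenario = sd.SyntheticScenario(
        n_genes=15, seed=3, coverage_reads_per_kb=300, junction_depth=8,
        gene_length_log2_mean=12.0,
    )
    ann = sd.simulate_annotation(scenario)
    counts = sd.simulate_counts(scenario, ann)
    sam = tmp_path_factory.mktemp("reads") / "reads.sam"
    sd.simulate_reads(scenario, ann, counts, sam)
    return scenario, ann, counts, sam


@pytest.fixture(scope="session")
def maxent_models():
    from ctsplice.features import build_synthetic_models

    return build_synthetic_models(n_training=800, seed=7)


def make_read(header, chrom, start, cigar, reverse, name="r", read2=False):
    """Construct an in-memory aligned read for counting tests."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    length = sum(ln for op, ln in cigar if op in (0, 1, 4))
    a.query_sequence = "A" * length
    a.reference_id = header.get_tid(chrom)
    a.reference_start = start
    a.cigartuples = cigar
    a.mapping_quality = 60
    flag = 0
    if reverse:
        flag |= 16
    if read2:
        flag |= 1 | 128
    a.flag = flag
    return a


@pytest.fixture
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
    )
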