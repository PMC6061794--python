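import numpy as np
import pytest

from poreqc import fixtures
from poreqc.model import ReadRecord, ReadTable


@pytest.fixture(scope="session")
def fastq_small(tmp_path_factory):
    """200-read synthetic FASTQ with its truth table."""
    d = tmp_path_factory.mktemp("fastq_small")
    path, truth = fixtures.make_fastq(d / "reads.fastq", n=200, seed=11)
    return path, truth


@pytest.fixture(scope="session")
def summary_small(tmp_path_factory):
    d = tmp_path_factory.mktemp("summary_small")
    path, truth = fixtures.make_summary(
        d / "summary.tsv", n=400, channels=512, run_hours=30.0, seed=12
    )
    return path, truth


@pytest.fixture(scope="session")
def sam_small(tmp_path_factory):
    d = tmp_path_factory.mktemp("sam_small")
    path, truth = fixtures.make_alignments(
        d / "aln.sam", n=300, identity=0.9, partial_fraction=0.4, seed=13
    )
    return path, truth


@pytest.fixture
def timed_table():
    """Hand-built table with times, channels and qualities."""
    rng = np.random.default_rng(7)
    records = [
        ReadRecord(
            read_id=f"r{i}",
            length=int(rng.integers(100, 5000)),
            mean_quality=float(rng.uniform(5, 15)),
            start_time=float(rng.uniform(0, 20 * 3600)),
            channel=int(rng.integers(1, 513)),
        )
        for i in range(50)
    ]
    return ReadTable(label="timed", records=records, source_kind="summary")
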