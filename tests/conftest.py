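import pytest

from lochip import ReadRecord, build_genome_model


@pytest.fixture(scope="session")
def small_genome():
    """10 Mb single-chromosome genome, no repeats, 100 annotated genes."""
    return build_genome_model(1, 10_000_000, 0.0, 100, seed=7)


@pytest.fixture(scope="session")
def repeat_genome():
    """5 Mb genome with ~10% repeat blocks and 50 genes."""
    return build_genome_model(1, 5_000_000, 0.1, 50, seed=3)


def make_read(read_id, chrom="chr1", start=1000, strand="+", cls="unique", mol=None):
    return ReadRecord(read_id, cls, None if cls == "unmapped" else chrom,
                      None if cls == "unmapped" else start,
                      None if cls == "unmapped" else strand, mol)
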