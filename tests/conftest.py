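import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from nanochrom.genome_io import SequenceRecord
from nanochrom.synthetic import SimSpec
import nanochrom as nc


@pytest.fixture(scope="session")
def small_genome():
    """A 60-chromosome mutation-free genome with its gene models and truth."""
    spec = SimSpec(n_chromosomes=60, seed=101, mu=0.0)
    records, genes, manifest = nc.simulate_genome(spec)
    return records, genes, manifest


@pytest.fixture(scope="session")
def small_classes(small_genome):
    records, _, _ = small_genome
    return nc.classify_genome(records)


def make_contig(
    contig_id="c1",
    subtel5="A" * 40,
    gene_seq="ATG" + "AAA" * 20 + "TGA",
    subtel3="T" * 40,
    units=2,
    has5=True,
    has3=True,
    coverage=10.0,
):
    """Hand-built plus-strand nanochromosome for coordinate arithmetic tests."""
    tel5 = "CCCCAAAA" * units if has5 else ""
    tel3 = "TTTTGGGG" * units if has3 else ""
    seq = tel5 + subtel5 + gene_seq + subtel3 + tel3
    cds_start = len(tel5) + len(subtel5) + 1
    cds_end = cds_start + len(gene_seq) - 1
    return SequenceRecord(contig_id, seq, coverage), cds_start, cds_end
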