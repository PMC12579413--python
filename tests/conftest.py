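import pytest

from polledrec.locus_model import Diplotype, allele_spec, build_haplotype
from polledrec.synthetic_data import (
    ReadSimParams,
    make_reference,
    project_alignments,
    simulate_reads,
)


@pytest.fixture(scope="session")
def segment():
    return make_reference(seed=101)


@pytest.fixture(scope="session")
def hap_p(segment):
    return build_haplotype(segment, allele_spec("p"))


@pytest.fixture(scope="session")
def hap_pf(segment):
    return build_haplotype(segment, allele_spec("P_F"))


@pytest.fixture(scope="session")
def hap_pc(segment):
    return build_haplotype(segment, allele_spec("P_C"))


@pytest.fixture(scope="session")
def pf_hom_alignments(segment, hap_pf):
    """Projected alignments of a homozygous P_F individual at 16x."""
    d = Diplotype("PFhom", "sire", (hap_pf, hap_pf))
    reads = simulate_reads(d, ReadSimParams(coverage=16.0, seed=42))
    aligns = project_alignments(reads, d)
    return d, reads, aligns
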