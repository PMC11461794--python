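import numpy as np
import pytest

from duplexmut.model import DepthProfile, VariantCall, VariantType
from duplexmut.simulate import GeneratorConfig, generate_cohort, generate_panel


def make_snv(sample="s1", chrom="locus01", pos=100, ref="C", alt="T",
             alt_count=1, site_depth=20000):
    return VariantCall(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        vtype=VariantType.SNV, alt_count=alt_count, site_depth=site_depth,
    )


@pytest.fixture(scope="session")
def panel():
    """Standard 20-locus, 2.4 kb synthetic panel."""
    return generate_panel(n_loci=20, locus_len=2400, gc_fraction=0.41, seed=7)


@pytest.fixture(scope="session")
def small_panel():
    return generate_panel(n_loci=2, locus_len=400, gc_fraction=0.5, seed=3)


@pytest.fixture(scope="session")
def uniform_depth(panel):
    arrays = {loc.contig_name: np.full(len(loc), 25000, dtype=np.int64) for loc in panel}
    return DepthProfile.from_arrays("s1", arrays, panel)


@pytest.fixture(scope="session")
def small_cohort(panel):
    """Scaled-down matched cohort (2 blood + 2 sperm, 0.2 Gb/sample)."""
    blood = GeneratorConfig.blood(seed=11, n_samples=2, duplex_bases_per_sample=200_000_000)
    sperm = GeneratorConfig.sperm(seed=11, n_samples=2, duplex_bases_per_sample=200_000_000)
    return generate_cohort([blood, sperm], panel, seed=11)


@pytest.fixture(scope="session")
def study_cohort(panel):
    """Full-scale matched cohort (6 + 6 samples, ~1.25 Gb duplex bases each)."""
    blood = GeneratorConfig.blood(seed=5)
    sperm = GeneratorConfig.sperm(seed=5)
    return generate_cohort([blood, sperm], panel, seed=5)
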