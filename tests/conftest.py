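import numpy as np
import pytest

from imabc import IMParams, StudyDesign, paper_like_design


@pytest.fixture(scope="session")
def paper_design() -> StudyDesign:
    return paper_like_design()


@pytest.fixture
def small_design() -> StudyDesign:
    """A cheap 3-locus design for fast pipeline tests."""
    return StudyDesign(
        n_loci=3,
        locus_lengths=(1000, 1000, 1000),
        mu_per_locus=(1.47e-6,) * 3,
        n_chrom_pop1=8,
        n_chrom_pop2=6,
        generation_time=25.0,
    )


@pytest.fixture
def panmictic_params() -> IMParams:
    """Single-population limit: no split, equal sizes, no migration."""
    return IMParams(N_A=10000.0, N1=10000.0, N2=10000.0, s=0.5, t_years=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140930)
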