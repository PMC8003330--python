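import pytest

from glyatkin import (
    HAPLOTYPE_156SER_199CYS,
    HAPLOTYPE_17THR_156SER,
    REFERENCE_156SER,
    SimulationDesign,
)


@pytest.fixture
def ref_params():
    """Reference haplotype (156Asn>Ser) parameter set."""
    return REFERENCE_156SER


@pytest.fixture
def tt_params():
    return HAPLOTYPE_17THR_156SER


@pytest.fixture
def rc_params():
    return HAPLOTYPE_156SER_199CYS


@pytest.fixture
def noiseless_design():
    """Default substrate grid, single replicate, no noise."""
    return SimulationDesign(noise_cv=0.0, noise_floor=0.0, n_replicates=1)
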