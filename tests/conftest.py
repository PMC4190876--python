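import pytest

from pkdpanel import (SimConfig, generate_reference, load_discovery_cohort,
                      load_validation_cohort)


@pytest.fixture(scope="session")
def validation_records():
    return load_validation_cohort()


@pytest.fixture(scope="session")
def discovery_records():
    return load_discovery_cohort()


@pytest.fixture(scope="session")
def small_cfg():
    """A small, fast synthetic world: 10 exons of 90 bp, 10 samples."""
    return SimConfig(
        gene_length_bp=2000, n_exons=10, exon_length_bp=90, intron_length_bp=100,
        flank_bp=200, n_samples=10, mean_depth=150.0, leakage_rate=2.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    return generate_reference(small_cfg)
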