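import pytest

from aiedit.synthdata import CohortConfig, generate_reference, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Compact cohort for module-level tests: fast but fully featured."""
    return CohortConfig(
        n_patients=6, genome_length=60_000, n_genes=25, alu_fraction=0.30,
        n_edit_sites=60, n_snps=80, n_somatic=15, n_background=60,
        depth_mean_dna=50, depth_mean_rna=50, seq_error_rate=1e-3, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Error-free cohort: every surviving call traces to a planted event."""
    return CohortConfig(
        n_patients=6, genome_length=60_000, n_genes=25, alu_fraction=0.30,
        n_edit_sites=60, n_snps=80, n_somatic=15, n_background=40,
        depth_mean_dna=60, depth_mean_rna=60, seq_error_rate=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    return simulate_cohort(clean_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The discovery-style cohort at its default study conditions."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)
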