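import pytest

from secondhit import simulate as sim


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (study conditions), shared across tests."""
    return sim.simulate_cohort(seed=42)


@pytest.fixture(scope="session")
def proband(cohort):
    return cohort.proband


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for fast end-to-end tests."""
    cfg = sim.CohortConfig(
        n_snps=60, branch_mutation_rate=30.0, tumor_truncal_mutations=80,
        n_lineage_nodes=10,
    )
    return sim.simulate_cohort(cfg, seed=7)
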