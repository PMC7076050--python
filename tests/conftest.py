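import pytest

from smearshed import AnalysisConfig, CohortConfig, generate_cohort, run_pipeline
from smearshed.mcmc import McmcConfig


@pytest.fixture(scope="session")
def default_cohort():
    """A study-sized synthetic cohort (~192 samples from 126 women)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """A 500-subject cohort for calibration and parameter-recovery checks."""
    return generate_cohort(CohortConfig(seed=101, n_subjects=500))


@pytest.fixture(scope="session")
def default_pipeline(default_cohort):
    """Full pipeline run (default settings) on the study-sized cohort."""
    table, _ = default_cohort
    return run_pipeline(AnalysisConfig(seed=7), table=table)


@pytest.fixture()
def fast_mcmc():
    """Short chains for tests that only need a rough posterior."""
    return McmcConfig(n_chains=2, n_iterations=1500, n_warmup=750, seed=5)
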