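import pytest

from mthet import calling, concordance, simulate


@pytest.fixture(scope="session")
def thresholds():
    return calling.Thresholds()


@pytest.fixture(scope="session")
def small_config():
    """Two donors, one time point, three platform-A replicates per group."""
    return simulate.StudyConfig(n_donors=2, n_technical_donors=0,
                                n_timepoints=1, replicates_per_timepoint=3)


@pytest.fixture(scope="session")
def small_study(small_config):
    """A fully simulated small study with planted truth (seed 1)."""
    return simulate.simulate_study(small_config, seed=1)


@pytest.fixture(scope="session")
def small_study_results(small_study, thresholds):
    """Calls and confirmation results for the small study."""
    calls = {lib: calling.call_library(df, thresholds, library_id=lib)
             for lib, df in small_study.counts.items()}
    results = concordance.confirm(calls, small_study.manifest, thresholds,
                                  counts_by_library=small_study.counts)
    return calls, results
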