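import pytest

from imprintscreen.pipeline import RunConfig, run_all


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default synthetic truth set (seed 1)."""
    return run_all(RunConfig(seed=1))


@pytest.fixture(scope="session")
def default_truth(default_run):
    return default_run.truth
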