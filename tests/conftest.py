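import pytest

from srnaphase import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def default_report():
    """One full pipeline run at the default study configuration.

    Shared across test modules; nothing in the suite mutates it.
    """
    return run_pipeline(RunConfig())


@pytest.fixture(scope="session")
def small_config():
    cfg = RunConfig()
    cfg.synthetic.n_reads_per_lib = 30_000
    return cfg
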