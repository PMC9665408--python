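import pytest

from rba_select import default_config, load_novrba_fixture, run_pipeline


@pytest.fixture(scope="session")
def novrba():
    return load_novrba_fixture()


@pytest.fixture(scope="session")
def novrba_report(novrba):
    return run_pipeline(
        novrba.config(),
        novrba.profiles_a,
        novrba.profiles_b,
        novrba.checklist,
        novrba.outcome_links,
    )


@pytest.fixture()
def cfg():
    return default_config()
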