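import pytest

from cttpower import generate_experiment, moment_match


@pytest.fixture(scope="session")
def default_table():
    """One seeded draw of the default two-condition experiment."""
    return generate_experiment(seed=20160113)


@pytest.fixture(scope="session")
def matched_table(default_table):
    """The default experiment moment-matched to the printed group moments."""
    return moment_match(default_table)
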