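"""Shared fixtures; the end-to-end synthetic study is session-scoped."""

import pytest

from emgfault import StudyConfig, run_study


@pytest.fixture(scope="session")
def study():
    """Full seven-setting study on the desk-scale synthetic fixture.

    One synthetic subject (17 movements x 6 repetitions, 2 s movement / 1 s
    rest, 12 channels at 2 kHz), three contaminants x two degradation cases
    (single forearm electrode and the four-channel flexor/extensor +
    bicep/tricep case), three of the twenty repetition folds.
    """
    return run_study(StudyConfig(seed=0))
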