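"""Shared fixtures: small seeded sequence sets and their normative traces."""

import pytest

from adaplearn import (MagnitudeGenConfig, ProbabilityGenConfig,
                       generate_sequence_set, run_observer)


@pytest.fixture(scope="session")
def mag_seqs():
    return generate_sequence_set(MagnitudeGenConfig(), 30, seed=101)


@pytest.fixture(scope="session")
def prob_seqs():
    return generate_sequence_set(ProbabilityGenConfig(), 30, seed=202)


@pytest.fixture(scope="session")
def mag_norms(mag_seqs):
    return [run_observer(s) for s in mag_seqs]


@pytest.fixture(scope="session")
def prob_norms(prob_seqs):
    return [run_observer(s) for s in prob_seqs]
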