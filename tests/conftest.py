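import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from nephrohmm import cthmm, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by tests that only need plausible data."""
    cfg = synthetic.SyntheticConfig(seed=90210, n_cohort1=120, n_cohort2=80)
    return synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    trajs = cthmm.trajectories_from_table(small_cohort.visits)
    fit = cthmm.fit_hmm(trajs, cthmm.FitConfig(seed=11, n_starts=3))
    return trajs, fit
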