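import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # hypothesis-based tests will be skipped by their own imports
    pass

from entroscan.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort: 10+10 subjects, 12 regions (3 planted), 120 points."""
    cfg = SynthConfig(
        n_per_group=(10, 10),
        n_regions=12,
        n_timepoints=120,
        planted_regions=(0, 4, 8),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort: 30+30 subjects, 90 regions, 175 points."""
    return generate_cohort(SynthConfig(seed=17))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
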