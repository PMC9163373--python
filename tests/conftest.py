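import dataclasses

import pytest

from famhist.lexicon import load_lexicon
from famhist.synth import SyntheticCorpusConfig, generate_cohort


@pytest.fixture(scope="session")
def zh_lexicon():
    return load_lexicon("zh")


@pytest.fixture(scope="session")
def debug_lexicon():
    return load_lexicon("debug")


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort (no negation phrases, no distractors), zh lexicon."""
    cfg = SyntheticCorpusConfig(
        n_patients=250, negation_rate=0.0, distractor_rate=0.0, seed=71
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort with default negation/distractor rates, zh lexicon."""
    cfg = SyntheticCorpusConfig(n_patients=250, seed=72)
    return generate_cohort(cfg)


@pytest.fixture
def float64_grads():
    """Run autograd in float64 for finite-difference comparisons."""
    import numpy as np

    from famhist.nn import autograd

    autograd.set_dtype(np.float64)
    yield
    autograd.set_dtype(np.float32)


def make_config(**overrides) -> SyntheticCorpusConfig:
    return dataclasses.replace(SyntheticCorpusConfig(), **overrides)
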