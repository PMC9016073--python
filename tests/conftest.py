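import numpy as np
import pytest

import spafnirs as sp
from spafnirs.synthetic import GeneratorConfig, generate_dyad


@pytest.fixture(scope="session")
def default_dyad():
    """One dyad under the full default protocol (21 min)."""
    return generate_dyad(GeneratorConfig(seed=11), familiarity="familiar")


@pytest.fixture(scope="session")
def default_pre(default_dyad):
    return sp.synchronize_and_segment(default_dyad)


@pytest.fixture(scope="session")
def default_wtc_set(default_pre):
    """All band-median coherence series of the default dyad (expensive)."""
    return sp.dyad_wtc_set(default_pre)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_config(seed: int = 0, **kwargs) -> GeneratorConfig:
    """A shortened protocol (30 s prebaseline + two 150 s segments) used
    where the full 21-minute session would only add runtime."""
    defaults = dict(
        session_duration=330.0, prebaseline=30.0, segment_durations=(150.0, 150.0)
    )
    defaults.update(kwargs)
    return GeneratorConfig(seed=seed, **defaults)
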