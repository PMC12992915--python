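import numpy as np
import pytest

import tractplast as tp


@pytest.fixture
def small_effect_config():
    """One-tract cohort with a localized two-metric effect at MRI3."""
    def make(seed=0, **overrides):
        kwargs = dict(
            tracts=("ATR_right",),
            n_segments=8,
            effects=[tp.EffectTemplate(
                "ATR_right", (4, 5),
                {"FISO": -0.8, "FICVF": -0.6},
                group_magnitude=1.0, subject_sd=0.4)],
            seed=seed,
        )
        kwargs.update(overrides)
        return tp.CohortConfig(**kwargs)
    return make


@pytest.fixture
def null_config():
    """Effect-free cohort factory (control of false-positive behavior)."""
    def make(seed=0, **overrides):
        kwargs = dict(tracts=("CST_left",), n_segments=10, effects=[], seed=seed)
        kwargs.update(overrides)
        return tp.CohortConfig(**kwargs)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
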