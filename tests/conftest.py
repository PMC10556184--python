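import numpy as np
import pytest

from pupilkit import ModelSpec, SyntheticSpec, simulate_dataset

CODING = {"condition": {"ctrl": -0.5, "exp": 0.5}}


def model_spec(**kw):
    kw.setdefault("dependent", "pupil_cue")
    kw.setdefault("fixed", ["condition"])
    kw.setdefault("coding", dict(CODING))
    return ModelSpec(**kw)


def null_spec(seed, **kw):
    """A true-null reduced-grid dataset spec: 50 samples on a 20 Hz
    (post-downsampling-like) grid, no condition effect of any kind."""
    d = dict(
        n_participants=10,
        trials_per_participant=20,
        rate_hz=20.0,
        epoch_ms=2500.0,
        conditions={"ctrl": 0.0, "exp": 0.0},
        effect_window_ms=(750.0, 2500.0),
        blink_rate=0.0,
        slope_sd=0.0,
        seed=seed,
    )
    d.update(kw)
    return SyntheticSpec(**d)


@pytest.fixture(scope="session")
def small_dataset():
    """A small default-regime dataset (with blinks) shared across tests."""
    spec = SyntheticSpec(n_participants=4, trials_per_participant=10, seed=3)
    return simulate_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
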