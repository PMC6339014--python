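import numpy as np
import pytest

import rfctsr as rf


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_pair():
    """One registered 64x64 (LD, HD) phantom pair at quarter dose."""
    hd = rf.make_phantom(rf.PhantomSpec(size=64, seed=7))
    ld = rf.simulate_low_dose(hd, rf.DoseModel(seed=8))
    return ld, hd


@pytest.fixture()
def identity_corpus():
    """Noise-free corpus where LD == HD (dose 1, sigma 0)."""
    spec = rf.PhantomSpec(size=64, seed=11)
    dose = rf.DoseModel(dose_fraction=1.0, base_sigma=0.0, seed=12)
    return rf.make_training_set(3, spec, dose)
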