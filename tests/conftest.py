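import numpy as np
import pytest

from widefc import synth


@pytest.fixture(scope="session")
def small_parcellation():
    return synth.make_ground_truth_parcellation(n_pairs=4, image_shape=(32, 32), seed=7)


@pytest.fixture(scope="session")
def short_task_log():
    return synth.simulate_task_log(trial_length=120.0, seed=11)


@pytest.fixture(scope="session")
def rendered_trial(small_parcellation):
    """A short rendered dual-channel trial with null effects."""
    eff = synth.EffectSpec()
    log = synth.simulate_task_log(60.0, seed=5)
    src = synth.simulate_sources(small_parcellation, log, eff, seed=6)
    blue, violet = synth.render_dual_channel_stack(src, small_parcellation, eff, seed=8)
    return {"log": log, "sources": src, "blue": blue, "violet": violet,
            "effects": eff, "parcellation": small_parcellation}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
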