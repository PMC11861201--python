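import numpy as np
import pytest

import myoface as mf


@pytest.fixture(scope="session")
def small_cfg():
    """One participant, six repetitions, default noise."""
    cfg = mf.ExperimentConfig(seed=7)
    cfg.generator = mf.GeneratorConfig(seed=7, n_participants=1, n_repetitions=6)
    cfg.n_train_trials = 4
    cfg.keypoint_folds = 4
    return cfg


@pytest.fixture(scope="session")
def participant_run(small_cfg):
    """Fully prepared participant (preprocessed, reordered, decomposed)."""
    return mf.prepare_participant(small_cfg, 0)


@pytest.fixture(scope="session")
def zero_noise_task():
    gen = mf.GeneratorConfig(seed=11, n_participants=1, n_repetitions=4,
                             noise=mf.NoiseConfig(0, 0, 0, 0))
    return gen, mf.generate_expression_task(gen, 0), mf.generate_mvc_task(gen, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
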