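import logging

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from erdscope import model, synthetic, tfmaps

# training progress logs are noise under pytest
logging.getLogger("erdscope").setLevel(logging.ERROR)


SMALL_ARCH = model.ArchConfig(conv_channels=(2,), pool=2, embed=(16,),
                              head_hidden=(8,))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small strong-effect cohort: fast to train on, easy to classify."""
    truth = synthetic.GroundTruth(seed=11, effect_size=2.0,
                                  subject_confound_scale=0.15,
                                  session_shift_scale=0.1)
    return synthetic.simulate_tf_cohort(4, 4, 30, truth, noise_sd=0.2)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    return tfmaps.build_pair_dataset(tiny_cohort.baseline, tiny_cohort.post,
                                     tiny_cohort.groups)


@pytest.fixture(scope="session")
def trained_tiny_bundle(tiny_dataset):
    split = model.make_split(tiny_dataset, "timepoint_80_20", seed=11)
    bundle = model.build_models(SMALL_ARCH, tiny_dataset.n_subjects, seed=11,
                                lam=0.0, input_shape=(64, 55))
    bundle, history = model.train(
        bundle, tiny_dataset, split,
        model.TrainConfig(epochs=4, batch_size=64, lr=3e-3, val_eval_cap=200))
    return bundle, history, split
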