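import numpy as np
import pytest

from adaptivenf import decode, preproc, synthdata, taskdesign


@pytest.fixture(scope="session")
def training_design():
    return taskdesign.build_training_design(2.0, seed=1)


@pytest.fixture(scope="session")
def feedback_design():
    return taskdesign.build_feedback_design(2.0, seed=2)


@pytest.fixture(scope="session")
def control_spec():
    return synthdata.make_subject_spec("control", seed=7, overrides={})


@pytest.fixture(scope="session")
def trained_model(control_spec, training_design):
    """SVM trained on one z-scored training run of the default control subject."""
    volumes, _, _ = synthdata.generate_run(control_spec, training_design)
    feats = preproc.normalize(volumes.to_features(), "zscore")
    return decode.train_classifier(feats, training_design.tr_labels)


@pytest.fixture(scope="session")
def separable_clouds():
    """Two linearly separable Gaussian clouds, 30 samples per class."""
    rng = np.random.default_rng(42)
    n = 30
    x_pos = rng.normal(loc=+3.0, scale=0.5, size=(n, 5))
    x_neg = rng.normal(loc=-3.0, scale=0.5, size=(n, 5))
    X = np.vstack([x_pos, x_neg])
    y = np.concatenate([np.ones(n, dtype=int), -np.ones(n, dtype=int)])
    return X, y
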