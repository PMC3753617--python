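import numpy as np
import pytest

from mirduplex import (
    ModelParams,
    SyntheticSpec,
    build_examples,
    simulate_hairpins,
    train,
)
from mirduplex.features import HairpinFeaturizer


def featurize_examples(examples):
    """Feature matrix + labels for a list of LabeledExamples."""
    featurizers = {}
    X, y = [], []
    for ex in examples:
        fz = featurizers.setdefault(ex.hairpin.id, HairpinFeaturizer(ex.hairpin))
        X.append(fz.vector(ex.start, ex.length))
        y.append(ex.label)
    return np.vstack(X), np.array(y)


@pytest.fixture(scope="session")
def small_corpus():
    """60 clean synthetic hairpins (2% mismatch) with planted truth."""
    return simulate_hairpins(SyntheticSpec(n=60, seed=20, mismatch_rate=0.02))


@pytest.fixture(scope="session")
def small_training(small_corpus):
    return featurize_examples(build_examples(small_corpus, seed=20))


@pytest.fixture(scope="session")
def small_model(small_training):
    """A fast model (15 trees, 3 rounds) for prediction/CLI tests."""
    X, y = small_training
    return train(X, y, ModelParams(n_trees=15, boosting_rounds=3, base_seed=20))
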