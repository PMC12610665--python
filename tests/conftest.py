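import numpy as np
import pytest

import pcgnet as pn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_clean_dataset():
    """20 clean recordings per class with their MFCC maps (5 classes)."""
    recs = pn.synth_recordings(20, seed=42)
    X = pn.MFCCTransformer().fit_transform([sr.recording for sr in recs])
    y = np.array([sr.recording.label for sr in recs])
    return recs, X, y


def _planted_problem(seed):
    rng = np.random.default_rng(seed)
    planted = {"c0": 3, "c1": 9, "c2": 14}
    Xs, ys = [], []
    for cls, row in planted.items():
        for _ in range(40):
            m = rng.normal(0.0, 1.0, (17, 13))
            m[row] += 6.0
            Xs.append(m)
            ys.append(cls)
    X, y = np.stack(Xs), np.array(ys)
    clf = pn.WCNNClassifier(epochs=8, n_filters=(8, 12, 12), dense_units=32,
                            random_state=seed)
    clf.fit(X, y)
    return clf, X, y, planted


@pytest.fixture(scope="session")
def planted_row_problem():
    """Classification task where each class is a bright MFCC-dimension row.

    Used to verify that Grad-CAM attention localizes the discriminative
    input rows.
    """
    return _planted_problem(0)


@pytest.fixture(scope="session")
def planted_row_problems():
    """The planted-row task trained under several seeds, for the recall-over-
    seeds attention-localization property."""
    return [_planted_problem(seed) for seed in (0, 1, 2, 7)]
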