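"""Published fold-level confusion matrices for the five-class PCG benchmark.

Row/column order: AR (aortic stenosis), MR, MS, MVP, N.  Rows are actual
classes, columns predicted.  ``BALANCED_FOLDS`` come from the balanced
10-fold sampling design (20 test recordings per class per fold);
``RANDOM_FOLDS`` from the unconstrained design (100 test recordings per
fold).  Used as fixed inputs to recompute the reported cross-validation
metrics.
"""

import numpy as np

LABELS = ("AR", "MR", "MS", "MVP", "N")


def _diag(*counts):
    return np.diag(counts)


BALANCED_FOLDS = [
    np.array([
        [20, 0, 0, 0, 0],
        [0, 19, 1, 0, 0],
        [0, 0, 20, 0, 0],
        [1, 0, 0, 19, 0],
        [0, 0, 0, 0, 20],
    ]),
    _diag(20, 20, 20, 20, 20),
    _diag(20, 20, 20, 20, 20),
    _diag(20, 20, 20, 20, 20),
    _diag(20, 20, 20, 20, 20),
    np.array([
        [19, 1, 0, 0, 0],
        [0, 20, 0, 0, 0],
        [0, 0, 20, 0, 0],
        [0, 0, 0, 20, 0],
        [0, 0, 0, 0, 20],
    ]),
    np.array([
        [20, 0, 0, 0, 0],
        [0, 19, 1, 0, 0],
        [0, 0, 20, 0, 0],
        [0, 0, 0, 20, 0],
        [0, 0, 0, 0, 20],
    ]),
    _diag(20, 20, 20, 20, 20),
    _diag(20, 20, 20, 20, 20),
    _diag(20, 20, 20, 20, 20),
]

RANDOM_FOLDS = [
    _diag(19, 22, 26, 15, 18),
    np.array([
        [20, 0, 0, 0, 0],
        [0, 19, 0, 0, 0],
        [0, 0, 14, 0, 0],
        [0, 1, 0, 27, 0],
        [0, 0, 0, 0, 19],
    ]),
    np.array([
        [21, 0, 0, 0, 0],
        [0, 19, 0, 0, 0],
        [0, 0, 20, 0, 0],
        [2, 0, 0, 19, 0],
        [0, 0, 0, 0, 19],
    ]),
    np.array([
        [21, 0, 0, 0, 0],
        [0, 16, 0, 0, 0],
        [0, 0, 18, 0, 0],
        [0, 1, 0, 27, 0],
        [0, 0, 0, 0, 17],
    ]),
    _diag(16, 24, 25, 13, 22),
    _diag(14, 17, 17, 22, 30),
    np.array([
        [16, 1, 0, 0, 0],
        [0, 22, 0, 0, 0],
        [0, 0, 22, 0, 0],
        [0, 0, 0, 23, 0],
        [0, 0, 0, 0, 16],
    ]),
    _diag(21, 14, 21, 18, 26),
    _diag(24, 21, 20, 19, 16),
    np.array([
        [27, 0, 0, 0, 0],
        [0, 25, 1, 0, 0],
        [0, 0, 17, 0, 0],
        [0, 0, 0, 13, 0],
        [0, 0, 0, 0, 17],
    ]),
]
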