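import numpy as np
import pytest

from pvbcorrect import VerificationDataset


def make_dataset(cells_verified, unverified_t1=0, unverified_t0=0):
    """Build a dataset from verified (tp, fn, fp, tn) cell counts plus
    unverified subjects per test stratum."""
    tp, fn, fp, tn = cells_verified
    t = np.concatenate(
        [
            np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn),
            np.ones(unverified_t1), np.zeros(unverified_t0),
        ]
    )
    d = np.concatenate(
        [
            np.ones(tp + fn), np.zeros(fp + tn),
            np.full(unverified_t1 + unverified_t0, np.nan),
        ]
    )
    v = np.concatenate(
        [np.ones(tp + fn + fp + tn), np.zeros(unverified_t1 + unverified_t0)]
    )
    return VerificationDataset(t, d, v)


def brute_force_resampling_expectation(cells, sipw, size):
    """Independent oracle: expected (Sn, Sp) of a weighted resample of
    ``size`` draws, conditioned on a valid four-cell table, by exhaustive
    enumeration of all index tuples weighted by products of sipw."""
    cells = np.asarray(cells)
    sipw = np.asarray(sipw, dtype=float)
    k = cells.size
    tuples = np.indices((k,) * size).reshape(size, -1)  # size x k^size
    counts = np.stack([(cells[tuples] == c).sum(axis=0) for c in range(4)])
    weights = np.prod(sipw[tuples], axis=0)
    valid = (counts > 0).all(axis=0)
    w = weights[valid]
    sn = counts[0, valid] / (counts[0, valid] + counts[1, valid])
    sp = counts[3, valid] / (counts[2, valid] + counts[3, valid])
    return float((w * sn).sum() / w.sum()), float((w * sp).sum() / w.sum())


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def spec_example_pvb():
    """The worked example used across the direct estimators: 100
    subjects, 50 per test stratum; verified: 40 of T=1 (30 diseased),
    20 of T=0 (5 diseased)."""
    return make_dataset((30, 5, 10, 15), unverified_t1=10, unverified_t0=30)
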