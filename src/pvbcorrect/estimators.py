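"""Scikit-learn style estimator classes for PVB correction.

Each class wraps one correction method behind the familiar
``fit``/``get_params``/``set_params`` surface (fit-only estimators, in
the spirit of sklearn's covariance estimators): ``fit`` consumes
subject-level (test, disease, verified) data and exposes the fitted
sensitivity and specificity as ``sn_`` and ``sp_``.  The input may be a
:class:`~pvbcorrect.data.VerificationDataset`, a DataFrame with columns
``test``/``disease``/``verified``, or an (n, 2)/(n, 3) array of columns
in that order (NaN disease = unverified).

>>> est = SIPW(b=1000, random_state=0).fit(frame)
>>> est.sn_, est.sp_
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import VerificationDataset
from . import direct, imputation, resampling
from .resampling import BalanceSpec


def as_dataset(X) -> VerificationDataset:
    """Coerce supported inputs to a VerificationDataset."""
    if isinstance(X, VerificationDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return VerificationDataset.from_frame(X)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValueError(
            "expected a VerificationDataset, a DataFrame with columns "
            "test/disease/verified, or an (n, 2) or (n, 3) array; got "
            f"shape {getattr(arr, 'shape', None)}"
        )
    v = arr[:, 2] if arr.shape[1] == 3 else None
    return VerificationDataset(arr[:, 0], arr[:, 1], v)


class _AccuracyEstimator(BaseEstimator):
    """Common fit plumbing; subclasses implement ``_estimate``."""

    def fit(self, X, y=None):
        data = as_dataset(X)
        estimate = self._estimate(data)
        self.estimate_ = estimate
        self.sn_ = estimate.sn
        self.sp_ = estimate.sp
        self.n_features_in_ = 3
        return self

    def _estimate(self, data: VerificationDataset):  # pragma: no cover
        raise NotImplementedError


class FullDataAnalysis(_AccuracyEstimator):
    """Benchmark Sn/Sp on complete, fully verified data."""

    def _estimate(self, data):
        return direct.fda_estimate(data)


class CompleteCaseAnalysis(_AccuracyEstimator):
    """Naive Sn/Sp on verified subjects only (biased under PVB)."""

    def _estimate(self, data):
        return direct.cca_estimate(data)


class BeggGreenes(_AccuracyEstimator):
    """Begg–Greenes Bayes-inversion correction."""

    def _estimate(self, data):
        return direct.bg_estimate(data)


class InverseProbabilityWeighting(_AccuracyEstimator):
    """IPWE: Horvitz–Thompson weighting of the verified table."""

    def _estimate(self, data):
        return direct.ipwe_estimate(data)


class MultipleImputation(_AccuracyEstimator):
    """MI: m proper logistic imputations of missing disease status.

    Fitted attributes include ``draws_`` with the per-imputation
    estimates and within-imputation variances for Rubin pooling.
    """

    def __init__(self, m: int = 100, random_state: Optional[int] = None):
        self.m = m
        self.random_state = random_state

    def _estimate(self, data):
        rng = np.random.default_rng(self.random_state)
        estimate, self.draws_ = imputation.mi_estimate(data, m=self.m, rng=rng)
        return estimate


class _ResamplingEstimator(_AccuracyEstimator):
    """Shared surface for the weighted-resampling correctors.

    Fitted attributes include ``sn_samples_``/``sp_samples_``, the
    per-resample estimate lists retained for interval procedures.
    """

    def __init__(self, b: int = 1000, random_state: Optional[int] = None):
        self.b = b
        self.random_state = random_state

    def _lists(self, data, rng):  # pragma: no cover
        raise NotImplementedError

    def _estimate(self, data):
        rng = np.random.default_rng(self.random_state)
        estimate, self.sn_samples_, self.sp_samples_ = self._lists(data, rng)
        return estimate


class InverseProbabilityBootstrap(_ResamplingEstimator):
    """IPB: IPW-weighted bootstrap of the verified subset (size n1)."""

    def _lists(self, data, rng):
        return resampling.ipb_estimate(data, b=self.b, rng=rng)


class SIPW(_ResamplingEstimator):
    """Scaled IPW resampling: size-n resamples restoring the full sample."""

    def _lists(self, data, rng):
        return resampling.sipw_estimate(data, b=self.b, rng=rng)


class SIPWBalanced(_ResamplingEstimator):
    """SIPW-B: SIPW with diseased mass rebalanced to 1/(1+rel_size)."""

    def __init__(
        self, b: int = 1000, rel_size: float = 1.0, random_state: Optional[int] = None
    ):
        super().__init__(b=b, random_state=random_state)
        self.rel_size = rel_size

    def _lists(self, data, rng):
        return resampling.sipwb_estimate(
            data, b=self.b, spec=BalanceSpec(self.rel_size), rng=rng
        )


#: Registry used by the study harness and the CLI.
ESTIMATORS = {
    "fda": FullDataAnalysis,
    "cca": CompleteCaseAnalysis,
    "bg": BeggGreenes,
    "ipwe": InverseProbabilityWeighting,
    "mi": MultipleImputation,
    "ipb": InverseProbabilityBootstrap,
    "sipw": SIPW,
    "sipwb": SIPWBalanced,
}
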