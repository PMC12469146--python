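"""Propensity estimation and weighted-resampling bias correctors.

The three resampling correctors share one mechanism: verified subjects
are resampled with replacement with probabilities proportional to their
inverse-probability weights 1/PS, where PS = P(V=1|T) is the propensity
of verification.  They differ in the resample size and in an optional
class-rebalancing step:

* IPB   — inverse probability bootstrap: resamples of size n1 (the
          verified count), i.e. a weighted bootstrap of the verified
          subset only.
* SIPW  — scaled inverse-probability-weighted resampling: resamples of
          the full sample size n, restoring the complete sample.
* SIPW-B — SIPW with the diseased/non-diseased probability mass forced
          to a chosen control:case ratio (default 1:1), mimicking a
          case-control design to stabilise the sensitivity estimate at
          low prevalence.

Each resample must form a four-cell T-by-D table; invalid resamples are
discarded and redrawn.  Point estimates are the means of the
per-resample Sn and Sp over b valid resamples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import statsmodels.api as sm

from .data import (
    AccuracyEstimate,
    PVBDataError,
    VerificationDataset,
    cell_ids,
)


class PropensityError(ValueError):
    """Raised when the verification propensity model cannot be fitted."""


class ResamplingError(RuntimeError):
    """Raised when no valid resample can be drawn within the budget."""


@dataclass(frozen=True)
class WeightSet:
    """Per-verified-subject weights, aligned with ``index``.

    ps   — fitted propensity P(V=1|T) in (0, 1);
    ipw  — inverse-probability weight (1/ps, possibly rebalanced);
    sipw — scaled weight: ipw normalized to sum to one over the
           verified subjects, used as resampling probabilities.
    """

    index: np.ndarray
    ps: np.ndarray
    ipw: np.ndarray
    sipw: np.ndarray

    def __post_init__(self) -> None:
        total = self.sipw.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scaled weights sum to {total}, expected 1")


@dataclass(frozen=True)
class BalanceSpec:
    """Desired control:case relative size n_{D=0} : n_{D=1} for SIPW-B."""

    rel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.rel_size <= 0:
            raise ValueError(f"rel_size must be positive, got {self.rel_size}")


def fit_propensity(data: VerificationDataset) -> np.ndarray:
    """Logistic regression of V on T; returns fitted PS per subject.

    For a binary test the model is saturated, so the fitted propensity
    in stratum T=t equals the observed verification proportion there.
    A stratum that is entirely verified or entirely unverified makes
    the logit diverge (perfect separation); that is reported with
    guidance rather than returning boundary probabilities.
    """
    for t in (0, 1):
        mask = data.t == t
        if not mask.any():
            raise PropensityError(
                f"no subjects with T={t}; the propensity of verification "
                "given the test result is not identifiable"
            )
        rate = data.v[mask].mean()
        if rate == 0.0 or rate == 1.0:
            raise PropensityError(
                f"stratum T={t} is {'entirely' if rate else 'never'} verified; "
                "the logistic propensity model separates perfectly. Collect "
                "verified and unverified subjects in both test strata, or use "
                "a complete-data estimator if everything is verified."
            )
    exog = sm.add_constant(data.t.astype(float))
    fit = sm.GLM(data.v.astype(float), exog, family=sm.families.Binomial()).fit()
    ps = np.asarray(fit.predict(exog), dtype=float)
    return ps


def sipw_weights(data: VerificationDataset, ps: np.ndarray) -> WeightSet:
    """Scaled inverse-probability weights for verified subjects.

    ipw_i = 1/ps_i for V_i=1; sipw_i = ipw_i / sum(ipw) so the scaled
    weights form a probability vector over the verified subjects.
    """
    idx = data.verified_index
    if idx.size == 0:
        raise PVBDataError("no verified subjects to weight")
    ps_v = np.asarray(ps, dtype=float)[idx]
    if np.any(ps_v <= 0) or np.any(ps_v >= 1):
        raise PropensityError("propensity scores must lie strictly in (0, 1)")
    ipw = 1.0 / ps_v
    sipw = ipw / ipw.sum()
    return WeightSet(index=idx, ps=ps_v, ipw=ipw, sipw=sipw)


def sipwb_weights(
    data: VerificationDataset,
    ps: np.ndarray,
    spec: BalanceSpec = BalanceSpec(),
) -> WeightSet:
    """SIPW weights rebalanced to a target control:case mass ratio.

    Among verified subjects: the diseased IPWs are first multiplied by
    the observed relative size n_{D=0}/n_{D=1}, then by k/rel_size where
    k is the post-update ratio of non-diseased to diseased total weight.
    After normalization the diseased probability mass is exactly
    1/(1+rel_size).
    """
    base = sipw_weights(data, ps)
    d_v = data.d[base.index]
    diseased = d_v == 1
    n_d1 = int(diseased.sum())
    n_d0 = diseased.size - n_d1
    if n_d1 == 0 or n_d0 == 0:
        raise PVBDataError(
            "rebalancing requires verified subjects with and without disease"
        )
    ipw = base.ipw.copy()
    rel_init = n_d0 / n_d1
    ipw[diseased] *= rel_init
    k = ipw[~diseased].sum() / ipw[diseased].sum()
    ipw[diseased] *= k / spec.rel_size
    sipw = ipw / ipw.sum()
    return WeightSet(index=base.index, ps=base.ps, ipw=ipw, sipw=sipw)


# ---------------------------------------------------------------------
# resampling core
# ---------------------------------------------------------------------


def _resample_cell_counts(
    cells_v: np.ndarray,
    sipw: np.ndarray,
    size: int,
    b: int,
    rng: np.random.Generator,
    max_redraw_rounds: int = 1000,
) -> np.ndarray:
    """Draw b valid resamples; return their (b, 4) T-by-D cell counts.

    Subjects are drawn with replacement by inverse-CDF lookup over the
    scaled-weight CDF (all b resamples batched); any resample whose
    table has an empty cell is redrawn until valid or the budget is
    exhausted.
    """
    cdf = np.cumsum(sipw)
    cdf[-1] = 1.0
    counts = np.zeros((b, 4), dtype=np.int64)
    pending = np.arange(b)
    offsets4 = 4 * np.arange(b)
    for _ in range(max_redraw_rounds):
        k = pending.size
        idx = np.searchsorted(cdf, rng.random((k, size)), side="right")
        cells = cells_v[idx]
        flat = (cells + offsets4[pending, None]).ravel()
        counts_k = np.bincount(flat, minlength=4 * b).reshape(b, 4)[pending]
        counts[pending] = counts_k
        still_bad = (counts_k == 0).any(axis=1)
        if not still_bad.any():
            return counts
        pending = pending[still_bad]
    raise ResamplingError(
        f"{pending.size} of {b} resamples still had an empty T-by-D cell after "
        f"{max_redraw_rounds} redraw rounds; the weights are too degenerate to "
        "populate all four cells"
    )


def draw_valid_resample(
    data: VerificationDataset,
    weights: WeightSet,
    size: int,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> VerificationDataset:
    """Draw one subject-level resample whose T-by-D table is valid.

    Samples ``size`` verified subjects with replacement with probability
    ``sipw``; resamples with an empty cell are discarded and redrawn.
    """
    if size < 4:
        raise ValueError(f"resample size must be at least 4, got {size}")
    for _ in range(max_tries):
        pick = weights.index[
            np.searchsorted(np.cumsum(weights.sipw), rng.random(size), side="right").clip(
                max=weights.index.size - 1
            )
        ]
        resample = VerificationDataset(
            data.t[pick], data.d[pick], np.ones(size, dtype=np.int8)
        )
        counts = np.bincount(cell_ids(resample.t, resample.d), minlength=4)
        if np.all(counts > 0):
            return resample
    raise ResamplingError(f"no valid resample within {max_tries} tries")


def _mean_estimate(
    data: VerificationDataset,
    weights: WeightSet,
    size: int,
    b: int,
    rng: np.random.Generator,
    method: str,
) -> Tuple[AccuracyEstimate, np.ndarray, np.ndarray]:
    cells_v = cell_ids(data.t[weights.index], data.d[weights.index])
    counts = _resample_cell_counts(cells_v, weights.sipw, size, b, rng)
    sn_list = counts[:, 0] / (counts[:, 0] + counts[:, 1])
    sp_list = counts[:, 3] / (counts[:, 2] + counts[:, 3])
    est = AccuracyEstimate(
        sn=float(sn_list.mean()), sp=float(sp_list.mean()), method=method
    )
    return est, sn_list, sp_list


def _resolve_rng(rng) -> np.random.Generator:
    if rng is None or isinstance(rng, (int, np.integer)):
        return np.random.default_rng(rng)
    return rng


def sipw_estimate(
    data: VerificationDataset,
    b: int = 1000,
    rng=None,
    ps: Optional[np.ndarray] = None,
) -> Tuple[AccuracyEstimate, np.ndarray, np.ndarray]:
    """SIPW corrector: mean Sn/Sp over b valid resamples of size n.

    Returns the point estimate plus the per-resample Sn and Sp lists
    (retained for interval estimation).
    """
    rng = _resolve_rng(rng)
    if ps is None:
        ps = fit_propensity(data)
    weights = sipw_weights(data, ps)
    return _mean_estimate(data, weights, data.n, b, rng, "SIPW")


def sipwb_estimate(
    data: VerificationDataset,
    b: int = 1000,
    spec: BalanceSpec = BalanceSpec(),
    rng=None,
    ps: Optional[np.ndarray] = None,
) -> Tuple[AccuracyEstimate, np.ndarray, np.ndarray]:
    """SIPW-B corrector: SIPW with rebalanced diseased mass, size-n resamples."""
    rng = _resolve_rng(rng)
    if ps is None:
        ps = fit_propensity(data)
    weights = sipwb_weights(data, ps, spec)
    return _mean_estimate(data, weights, data.n, b, rng, "SIPW-B")


def ipb_estimate(
    data: VerificationDataset,
    b: int = 1000,
    rng=None,
    ps: Optional[np.ndarray] = None,
) -> Tuple[AccuracyEstimate, np.ndarray, np.ndarray]:
    """Inverse probability bootstrap: weighted bootstrap of size n1.

    Identical to SIPW except each resample matches the verified count
    n1, so only the verified portion of the sample is restored.  The
    per-resample lists double as the bootstrap distribution for IPB's
    native percentile interval.
    """
    rng = _resolve_rng(rng)
    if ps is None:
        ps = fit_propensity(data)
    weights = sipw_weights(data, ps)
    return _mean_estimate(data, weights, data.n1, b, rng, "IPB")
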