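"""Non-resampling estimators: FDA, CCA, Begg–Greenes and IPWE.

FDA (full data analysis) is the ideal benchmark on complete data; CCA
(complete case analysis) is the naive, biased estimator on verified
subjects only.  The Begg–Greenes correction rescales the verified-
stratum disease rates by the test-result marginal frequencies via
Bayes' theorem; the inverse probability weighting estimator (IPWE)
weights each verified subject by 1/P(V=1|T).  For a binary test with a
saturated propensity model the two corrections coincide exactly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .data import (
    AccuracyEstimate,
    CrossTable,
    PVBDataError,
    VerificationDataset,
    cell_ids,
    cross_tabulate,
    estimate_accuracy,
    table_from_counts,
)
from .resampling import fit_propensity


def fda_estimate(complete: VerificationDataset) -> AccuracyEstimate:
    """Sn/Sp from the full, completely verified dataset (benchmark)."""
    table = cross_tabulate(complete, verified_only=False)
    est = estimate_accuracy(table, method="FDA")
    return est


def cca_estimate(pvb: VerificationDataset) -> AccuracyEstimate:
    """Naive Sn/Sp from verified subjects only (biased under PVB)."""
    table = cross_tabulate(pvb, verified_only=True)
    return estimate_accuracy(table, method="CCA")


def bg_estimate(pvb: VerificationDataset) -> AccuracyEstimate:
    """Begg–Greenes correction.

    With s_t the number of subjects (verified or not) with T=t and
    d_t = P(D=1 | T=t, V=1) the verified-stratum disease rate:

        Sn = s1*d1 / (s1*d1 + s0*d0)
        Sp = s0*(1-d0) / (s1*(1-d1) + s0*(1-d0))

    Under MAR, d_t is a consistent estimate of P(D=1|T=t), so these are
    the Bayes-inverted accuracy measures.
    """
    s = np.array([np.sum(pvb.t == 0), np.sum(pvb.t == 1)], dtype=float)
    if s[0] == 0 or s[1] == 0:
        raise PVBDataError("both test strata must be nonempty for Begg–Greenes")
    d_rate = np.empty(2)
    for t in (0, 1):
        mask = (pvb.t == t) & (pvb.v == 1)
        if not mask.any():
            raise PVBDataError(
                f"no verified subjects with T={t}; P(D=1|T={t}) is not estimable"
            )
        d_rate[t] = np.mean(pvb.d[mask] == 1)
    num_sn = s[1] * d_rate[1]
    den_sn = s[1] * d_rate[1] + s[0] * d_rate[0]
    num_sp = s[0] * (1.0 - d_rate[0])
    den_sp = s[1] * (1.0 - d_rate[1]) + s[0] * (1.0 - d_rate[0])
    if den_sn == 0:
        raise PVBDataError("sensitivity undefined: estimated disease rate is zero in both strata")
    if den_sp == 0:
        raise PVBDataError("specificity undefined: estimated disease rate is one in both strata")
    return AccuracyEstimate(sn=float(num_sn / den_sn), sp=float(num_sp / den_sp), method="BG")


def ipwe_weighted_table(
    pvb: VerificationDataset, ps: Optional[np.ndarray] = None
) -> CrossTable:
    """Horvitz–Thompson weighted T-by-D table over verified subjects."""
    if ps is None:
        ps = fit_propensity(pvb)
    idx = pvb.verified_index
    ps_v = np.asarray(ps, dtype=float)[idx]
    # PS may equal 1 (a fully verified stratum contributes unit weights)
    if np.any(ps_v <= 0) or np.any(ps_v > 1):
        raise PVBDataError("propensity scores must lie in (0, 1]")
    weights = 1.0 / ps_v
    cells = cell_ids(pvb.t[idx], pvb.d[idx])
    counts = np.bincount(cells, weights=weights, minlength=4)
    return table_from_counts(counts)


def ipwe_estimate(
    pvb: VerificationDataset, ps: Optional[np.ndarray] = None
) -> AccuracyEstimate:
    """Inverse probability weighting estimator.

    Each verified subject contributes weight 1/PS to its (T, D) cell;
    Sn/Sp are read off the weighted table.  With the saturated
    propensity model on a binary test this equals the Begg–Greenes
    estimate on every dataset.
    """
    table = ipwe_weighted_table(pvb, ps)
    est = estimate_accuracy(table, method="IPWE")
    return est
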