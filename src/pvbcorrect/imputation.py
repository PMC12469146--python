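"""Multiple imputation of missing disease status.

Missing D values are imputed from a logistic regression of D on T
fitted to the verified subjects.  Imputation is "proper": for each of
the m completed datasets a fresh coefficient vector is drawn from the
asymptotic normal approximation of the fit, so between-imputation
variability reflects estimation uncertainty in P(D=1|T) as standard MI
software does.  Following the logistic method of standard MI software,
the fit is stabilised by White-style data augmentation: for each
outcome class, low-weight pseudo-observations are placed at the
predictor mean +/- one standard deviation (total pseudo weight equal to
the number of coefficients), which guards against perfect prediction
and regularises near-empty strata.  Per-imputation Sn/Sp estimates and
their Wald variances are retained for Rubin's-rules pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .data import (
    AccuracyEstimate,
    MISSING,
    PVBDataError,
    VerificationDataset,
    cross_tabulate,
)


class ImputationError(ValueError):
    """Raised when the disease model cannot support imputation."""


@dataclass(frozen=True)
class ImputationDraws:
    """Per-imputation estimates retained for Rubin pooling.

    ``var_sn``/``var_sp`` are the within-imputation Wald variances
    p(1-p)/denominator of each completed-data proportion.
    """

    sn: np.ndarray
    sp: np.ndarray
    var_sn: np.ndarray
    var_sp: np.ndarray

    @property
    def m(self) -> int:
        return int(self.sn.size)


@dataclass(frozen=True)
class _DiseaseModel:
    """Fitted logistic D~T model: coefficient mean and covariance."""

    beta: np.ndarray
    cov: np.ndarray

    def draw_rates(self, rng: np.random.Generator) -> Tuple[float, float]:
        """Draw (P(D=1|T=0), P(D=1|T=1)) from the asymptotic normal."""
        beta = rng.multivariate_normal(self.beta, self.cov, method="cholesky")
        return float(expit(beta[0])), float(expit(beta[0] + beta[1]))


def _augmented_design(t_all: np.ndarray, t_v: np.ndarray, d_v: np.ndarray):
    """White-style augmentation of the D~T fit.

    Adds, per outcome class, pseudo-observations at the predictor mean
    plus/minus one SD (clipped to the observed range), with the total
    pseudo weight p+1 split evenly — the stabilisation standard MI
    software applies to its logistic imputation model.
    """
    mean = t_all.mean()
    sd = t_all.std(ddof=1)
    lo, hi = t_all.min(), t_all.max()
    pseudo_t = np.clip(np.array([mean + sd, mean - sd]), lo, hi)
    t_aug = np.concatenate([np.tile(pseudo_t, 2), t_v])
    d_aug = np.concatenate([[0.0, 0.0, 1.0, 1.0], d_v])
    n_pseudo = 4  # 2 * p * k with one predictor, two classes
    weights = np.concatenate([np.full(n_pseudo, 2.0 / n_pseudo), np.ones(t_v.size)])
    return t_aug, d_aug, weights


def fit_disease_model(pvb: VerificationDataset) -> _DiseaseModel:
    """Augmented logistic regression of D on T among verified subjects."""
    idx = pvb.verified_index
    if idx.size == 0:
        raise ImputationError("no verified subjects to fit the disease model")
    t_v = pvb.t[idx].astype(float)
    d_v = pvb.d[idx].astype(float)
    for t in (0, 1):
        mask = t_v == t
        if not mask.any():
            raise ImputationError(
                f"no verified subjects with T={t}; P(D|T) is not estimable"
            )
        rate = d_v[mask].mean()
        if rate == 0.0 or rate == 1.0:
            raise ImputationError(
                f"verified stratum T={t} has disease rate {rate:.0f}: the logistic "
                "imputation model separates perfectly. Consider the Begg–Greenes "
                "or IPW estimators, which do not model P(D|T) parametrically."
            )
    t_aug, d_aug, weights = _augmented_design(pvb.t.astype(float), t_v, d_v)
    exog = sm.add_constant(t_aug)
    fit = sm.GLM(
        d_aug, exog, family=sm.families.Binomial(), freq_weights=weights
    ).fit()
    return _DiseaseModel(beta=np.asarray(fit.params), cov=np.asarray(fit.cov_params()))


def impute_once(
    pvb: VerificationDataset,
    rng: np.random.Generator,
    model: Optional[_DiseaseModel] = None,
) -> VerificationDataset:
    """One proper imputation: returns a completed dataset.

    A complete input is returned unchanged.  Otherwise coefficients are
    drawn from the fitted model's asymptotic normal and each missing D
    is drawn Bernoulli with the corresponding stratum probability.
    """
    if pvb.is_complete:
        return pvb
    if model is None:
        model = fit_disease_model(pvb)
    p0, p1 = model.draw_rates(rng)
    missing = pvb.d == MISSING
    prob = np.where(pvb.t[missing] == 1, p1, p0)
    d = pvb.d.copy()
    d[missing] = (rng.random(missing.sum()) < prob).astype(np.int8)
    return VerificationDataset(pvb.t, d, np.ones(pvb.n, dtype=np.int8))


def mi_estimate(
    pvb: VerificationDataset,
    m: int = 100,
    rng=None,
) -> Tuple[AccuracyEstimate, ImputationDraws]:
    """Multiple-imputation estimate: mean Sn/Sp over m completed datasets."""
    if m < 2:
        raise ValueError(f"need m >= 2 imputations for pooling, got {m}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    model = None if pvb.is_complete else fit_disease_model(pvb)
    sn = np.empty(m)
    sp = np.empty(m)
    var_sn = np.empty(m)
    var_sp = np.empty(m)
    for j in range(m):
        completed = impute_once(pvb, rng, model)
        table = cross_tabulate(completed)
        diseased = table.tp + table.fn
        nondiseased = table.fp + table.tn
        if diseased == 0 or nondiseased == 0:
            raise PVBDataError("completed dataset lost a disease class entirely")
        sn[j] = table.tp / diseased
        sp[j] = table.tn / nondiseased
        var_sn[j] = sn[j] * (1.0 - sn[j]) / diseased
        var_sp[j] = sp[j] * (1.0 - sp[j]) / nondiseased
    est = AccuracyEstimate(sn=float(sn.mean()), sp=float(sp.mean()), method="MI")
    return est, ImputationDraws(sn=sn, sp=sp, var_sn=var_sn, var_sp=var_sp)
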