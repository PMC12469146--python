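"""Confidence-interval procedures for the PVB estimators.

Four interval flavours are provided, matching how each estimator is
typically reported: a Wald interval for the naive complete-case
proportions, a nonparametric bootstrap percentile interval (whole
subject records resampled so the missingness pattern travels with the
data), Rubin's-rules pooling for multiple imputation, and the
percentile interval read directly off the weighted-resampling lists
that IPB already produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import stats

from .data import AccuracyEstimate, VerificationDataset
from .imputation import ImputationDraws

#: Quantile rule used for all percentile intervals (recorded in output
#: metadata because percentile dialects differ between packages).
PERCENTILE_RULE = "linear"


@dataclass(frozen=True)
class IntervalEstimate:
    lower: float
    upper: float
    level: float = 0.95
    method: str = ""
    replicates: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level must lie in (0, 1), got {self.level}")
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def wald_ci(p_hat: float, denom: float, level: float = 0.95) -> IntervalEstimate:
    """Normal-approximation interval p_hat ± z·sqrt(p_hat(1−p_hat)/denom)."""
    if denom <= 0:
        raise ValueError(f"denominator must be positive, got {denom}")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / denom)
    return IntervalEstimate(
        lower=float(max(0.0, p_hat - half)),
        upper=float(min(1.0, p_hat + half)),
        level=level,
        method="wald",
    )


def _percentiles(samples: np.ndarray, level: float) -> Tuple[float, float]:
    alpha = 1.0 - level
    lo, hi = np.quantile(samples, [0.5 * alpha, 1.0 - 0.5 * alpha], method=PERCENTILE_RULE)
    return float(lo), float(hi)


def bootstrap_percentile_ci(
    estimator: Callable[[VerificationDataset], AccuracyEstimate],
    data: VerificationDataset,
    R: int = 1000,
    level: float = 0.95,
    rng=None,
    max_redraws: Optional[int] = None,
) -> Tuple[IntervalEstimate, IntervalEstimate]:
    """Nonparametric bootstrap percentile intervals for (Sn, Sp).

    Whole subject records (T, D-or-missing, V) are resampled with
    replacement, size n, so the verification pattern is bootstrapped
    together with the data.  Bootstrap datasets on which the estimator
    fails (e.g. an empty verified cell) are redrawn under a budget.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    estimator(data)  # must succeed on the original data
    if max_redraws is None:
        max_redraws = 10 * R
    sn = np.empty(R)
    sp = np.empty(R)
    done = 0
    attempts = 0
    while done < R:
        if attempts >= R + max_redraws:
            raise RuntimeError(
                f"bootstrap redraw budget exhausted after {attempts} attempts "
                f"({done} of {R} replicates succeeded)"
            )
        attempts += 1
        pick = rng.integers(0, data.n, size=data.n)
        resample = VerificationDataset(data.t[pick], data.d[pick], data.v[pick])
        try:
            est = estimator(resample)
        except Exception:
            continue
        sn[done], sp[done] = est.sn, est.sp
        done += 1
    sn_lo, sn_hi = _percentiles(sn, level)
    sp_lo, sp_hi = _percentiles(sp, level)
    label = f"bootstrap-percentile[{PERCENTILE_RULE}]"
    return (
        IntervalEstimate(sn_lo, sn_hi, level, label, R),
        IntervalEstimate(sp_lo, sp_hi, level, label, R),
    )


def ipb_native_ci(
    samples: np.ndarray, level: float = 0.95, min_b: int = 100
) -> IntervalEstimate:
    """Percentile interval from stored per-resample estimates.

    IPB's b weighted-bootstrap resamples already form a bootstrap
    distribution, so no extra resampling is needed.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < min_b:
        raise ValueError(
            f"need at least {min_b} per-resample estimates, got {samples.size}"
        )
    lo, hi = _percentiles(samples, level)
    return IntervalEstimate(
        lo, hi, level, f"ipb-native-percentile[{PERCENTILE_RULE}]", int(samples.size)
    )


def _rubin_one(
    estimates: np.ndarray, variances: np.ndarray, level: float
) -> IntervalEstimate:
    m = estimates.size
    point = estimates.mean()
    w_bar = variances.mean()
    b_var = estimates.var(ddof=1)
    total = w_bar + (1.0 + 1.0 / m) * b_var
    if total == 0.0:
        return IntervalEstimate(float(point), float(point), level, "rubin", m)
    if b_var == 0.0:
        # no between-imputation variability: normal interval on W alone
        z = stats.norm.ppf(0.5 * (1.0 + level))
        half = z * np.sqrt(total)
    else:
        df = (m - 1) * (1.0 + w_bar / ((1.0 + 1.0 / m) * b_var)) ** 2
        half = stats.t.ppf(0.5 * (1.0 + level), df) * np.sqrt(total)
    return IntervalEstimate(
        float(max(0.0, point - half)), float(min(1.0, point + half)), level, "rubin", m
    )


def rubin_ci(
    draws: ImputationDraws, level: float = 0.95
) -> Tuple[IntervalEstimate, IntervalEstimate]:
    """Rubin's-rules intervals for pooled MI sensitivity and specificity.

    Total variance W̄ + (1+1/m)·B with Rubin's degrees of freedom
    (m−1)(1 + W̄/((1+1/m)B))²; a zero between-variance degenerates to
    the normal interval on the within variance alone.
    """
    if draws.m < 2:
        raise ValueError("Rubin pooling needs at least two imputations")
    return (
        _rubin_one(draws.sn, draws.var_sn, level),
        _rubin_one(draws.sp, draws.var_sp, level),
    )
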