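"""Synthetic PVB data generation.

Complete datasets follow a multinomial law over the four (T, D) cells
implied by prevalence p, sensitivity and specificity; partial
verification is then induced by a missing-at-random (MAR) mechanism in
which the probability of gold-standard verification depends only on the
test result: P(V=1|T=1) = lambda1, P(V=1|T=0) = lambda0.  The study
conditions default to the verification probabilities 0.8/0.4 commonly
used in PVB simulation work.

Generated dataset pairs are screened for validity: a dataset is usable
only if its 2x2 T-by-D table (and, for PVB data, the verified-only
table) has no zero cell, since every estimator downstream needs all
four cells populated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

from .data import MISSING, VerificationDataset, cross_tabulate


class ScenarioError(RuntimeError):
    """Raised when a simulation scenario cannot produce valid data."""


def _check_prob(value: float, name: str) -> None:
    if not (0.0 < value < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid.

    Defaults mirror the study conditions: verification probabilities
    lambda1=0.8, lambda0=0.4; B=500 simulation repetitions; b=1000
    resamples for the weighted-resampling correctors; m=100 imputations;
    R=1000 bootstrap replicates for interval estimation.
    """

    p: float
    sn_true: float
    sp_true: float
    n: int
    lambda1: float = 0.8
    lambda0: float = 0.4
    B: int = 500
    b: int = 1000
    m: int = 100
    R: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("p", "sn_true", "sp_true", "lambda1", "lambda0"):
            _check_prob(getattr(self, name), name)
        if self.n < 4:
            raise ValueError(f"n must be at least 4, got {self.n}")
        for name in ("B", "b", "m", "R"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def multinomial_cell_probs(
    p: float, sn_true: float, sp_true: float
) -> Tuple[float, float, float, float]:
    """Cell probabilities (pi1..pi4) of the complete-data multinomial.

    pi1 = P(T=1,D=1) = sn*p, pi2 = P(T=0,D=1) = (1-sn)*p,
    pi3 = P(T=1,D=0) = (1-sp)*(1-p), pi4 = P(T=0,D=0) = sp*(1-p).
    """
    for value, name in ((p, "p"), (sn_true, "sn_true"), (sp_true, "sp_true")):
        _check_prob(value, name)
    return (
        sn_true * p,
        (1.0 - sn_true) * p,
        (1.0 - sp_true) * (1.0 - p),
        sp_true * (1.0 - p),
    )


#: (T, D) realization for each multinomial category 1..4.
_CELL_TD = np.array([[1, 1], [0, 1], [1, 0], [0, 0]], dtype=np.int8)


def generate_complete(config: ScenarioConfig, rng: np.random.Generator) -> VerificationDataset:
    """Draw a fully verified dataset of size n from the cell multinomial."""
    probs = multinomial_cell_probs(config.p, config.sn_true, config.sp_true)
    cats = rng.choice(4, size=config.n, p=probs)
    t = _CELL_TD[cats, 0]
    d = _CELL_TD[cats, 1]
    return VerificationDataset(t, d, np.ones(config.n, dtype=np.int8))


def apply_mar_verification(
    complete: VerificationDataset,
    lambda1: float,
    lambda0: float,
    rng: np.random.Generator,
) -> VerificationDataset:
    """Mask disease status via test-dependent Bernoulli verification.

    V_i ~ Bernoulli(lambda1) if T_i=1 else Bernoulli(lambda0); D is set
    missing where V=0 and left untouched elsewhere.  lambda values of 0
    or 1 are allowed here (useful for identity/degenerate checks) even
    though the study scenarios keep them interior.
    """
    if not complete.is_complete:
        raise ValueError("apply_mar_verification expects a complete dataset")
    for lam, name in ((lambda1, "lambda1"), (lambda0, "lambda0")):
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {lam}")
    prob = np.where(complete.t == 1, lambda1, lambda0)
    v = (rng.random(complete.n) < prob).astype(np.int8)
    d = complete.d.copy()
    d[v == 0] = MISSING
    return VerificationDataset(complete.t, d, v)


def dataset_is_valid(data: VerificationDataset) -> bool:
    """Validity predicate: the relevant T-by-D table has no zero cell.

    For complete data the full table is checked; for PVB data the
    verified-only table is checked (every estimator consumes it).
    """
    table = cross_tabulate(data, verified_only=not data.is_complete)
    return table.valid


def generate_valid_scenario(
    config: ScenarioConfig,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> Tuple[VerificationDataset, VerificationDataset, int]:
    """Generate one (complete, pvb) pair passing the validity screen.

    Invalid draws (any zero cell in the complete table or in the PVB
    verified-only table) are discarded and regenerated, mirroring the
    discard-and-continue screening of the study design but with a retry
    budget.  Returns the pair plus the number of attempts used.
    """
    for attempt in range(1, max_attempts + 1):
        complete = generate_complete(config, rng)
        if not cross_tabulate(complete).valid:
            continue
        pvb = apply_mar_verification(complete, config.lambda1, config.lambda0, rng)
        verified = cross_tabulate(pvb, verified_only=True)
        if verified.valid:
            return complete, pvb, attempt
    raise ScenarioError(
        f"no valid dataset in {max_attempts} attempts for scenario "
        f"(p={config.p}, sn={config.sn_true}, sp={config.sp_true}, n={config.n}); "
        "the scenario is too sparse for a four-cell table"
    )


def iter_valid_pairs(
    config: ScenarioConfig, rng: np.random.Generator
) -> Iterator[Tuple[VerificationDataset, VerificationDataset]]:
    """Yield B valid (complete, pvb) pairs for one scenario."""
    for _ in range(config.B):
        complete, pvb, _attempts = generate_valid_scenario(config, rng)
        yield complete, pvb


def expected_verification_rate(config: ScenarioConfig) -> float:
    """Analytic overall verification probability P(V=1).

    P(T=1) = sn*p + (1-sp)(1-p); P(V=1) = lambda1*P(T=1) + lambda0*(1-P(T=1)).
    """
    p_t1 = config.sn_true * config.p + (1.0 - config.sp_true) * (1.0 - config.p)
    return config.lambda1 * p_t1 + config.lambda0 * (1.0 - p_t1)


#: The 12-scenario grid of the simulation study: two prevalences crossed
#: with six (Sn, Sp) pairs, each run at two sample sizes.
GRID_PREVALENCES: Tuple[float, ...] = (0.4, 0.1)
GRID_SNSP_PAIRS: Tuple[Tuple[float, float], ...] = (
    (0.3, 0.6),
    (0.3, 0.9),
    (0.6, 0.6),
    (0.6, 0.9),
    (0.9, 0.6),
    (0.9, 0.9),
)
GRID_SAMPLE_SIZES: Tuple[int, ...] = (200, 1000)


def grid_configs(
    prevalences: Sequence[float] = GRID_PREVALENCES,
    snsp_pairs: Sequence[Tuple[float, float]] = GRID_SNSP_PAIRS,
    sample_sizes: Sequence[int] = GRID_SAMPLE_SIZES,
    **overrides,
) -> Iterator[ScenarioConfig]:
    """Iterate ScenarioConfig over the full study grid (or a subset)."""
    for p in prevalences:
        for sn, sp in snsp_pairs:
            for n in sample_sizes:
                yield ScenarioConfig(p=p, sn_true=sn, sp_true=sp, n=n, **overrides)
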