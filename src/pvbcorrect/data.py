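"""Core domain types for partial-verification-bias (PVB) analysis.

A diagnostic accuracy study records, per subject, a binary index-test
result ``T``, a binary disease status ``D`` established by a gold
standard, and a verification indicator ``V``.  Under partial
verification only a subset of subjects (typically selected on the test
result) receives the gold standard, so ``D`` is missing exactly where
``V = 0``.  Everything downstream — the naive complete-case analysis,
the Begg–Greenes correction, inverse-probability weighting and the
weighted-resampling correctors — consumes the containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

#: Sentinel for unknown disease status (subject not verified).  Kept
#: distinct from the valid codes {0, 1} so that bookkeeping errors
#: (a disease value recorded for an unverified subject, or vice versa)
#: fail loudly instead of silently biasing estimates.
MISSING: int = -1

#: Cross-table cell order used throughout: (T=1,D=1), (T=0,D=1),
#: (T=1,D=0), (T=0,D=0) — i.e. TP, FN, FP, TN.
CELL_LABELS: Tuple[str, ...] = ("tp", "fn", "fp", "tn")


class PVBDataError(ValueError):
    """Raised when subject-level data violate the PVB bookkeeping rules."""


def _as_int8(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise PVBDataError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.dtype.kind == "f":
        out = np.full(arr.shape, MISSING, dtype=np.int8)
        finite = np.isfinite(arr)
        out[finite] = arr[finite].astype(np.int8)
        return out
    return arr.astype(np.int8)


@dataclass(frozen=True)
class VerificationDataset:
    """Subject-level (T, D, V) triples with D missing exactly where V=0.

    Parameters
    ----------
    t : array of {0, 1}
        Index test result (1 positive).
    d : array of {0, 1, MISSING}
        Gold-standard disease status; ``MISSING`` (−1) where unverified.
        Float input with NaN for missing values is accepted and recoded.
    v : array of {0, 1}, optional
        Verification status.  If omitted, inferred from ``d`` (verified
        where ``d`` is not missing).
    """

    t: np.ndarray
    d: np.ndarray
    v: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = _as_int8(self.t, "t")
        d = _as_int8(self.d, "d")
        if self.v is None:
            v = (d != MISSING).astype(np.int8)
        else:
            v = _as_int8(self.v, "v")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "v", v)
        n = t.shape[0]
        if n == 0:
            raise PVBDataError("empty dataset: no subjects")
        if d.shape[0] != n or v.shape[0] != n:
            raise PVBDataError(
                f"length mismatch: t has {n}, d has {d.shape[0]}, v has {v.shape[0]}"
            )
        if not np.isin(t, (0, 1)).all():
            raise PVBDataError("t must take values in {0, 1}")
        if not np.isin(v, (0, 1)).all():
            raise PVBDataError("v must take values in {0, 1}")
        if not np.isin(d, (0, 1, MISSING)).all():
            raise PVBDataError("d must take values in {0, 1} or be missing")
        bad = np.flatnonzero((v == 1) & (d == MISSING))
        if bad.size:
            raise PVBDataError(
                f"disease status missing for verified subjects at rows {bad[:5].tolist()}"
            )
        bad = np.flatnonzero((v == 0) & (d != MISSING))
        if bad.size:
            raise PVBDataError(
                f"disease status recorded for unverified subjects at rows {bad[:5].tolist()}"
            )

    # -- sizes ---------------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.t.shape[0])

    @property
    def n1(self) -> int:
        """Number of verified subjects."""
        return int(self.v.sum())

    @property
    def n0(self) -> int:
        """Number of unverified subjects."""
        return self.n - self.n1

    @property
    def is_complete(self) -> bool:
        """True when every subject is verified (no missing D)."""
        return self.n0 == 0

    @property
    def verified_index(self) -> np.ndarray:
        return np.flatnonzero(self.v == 1)

    def verified_subset(self) -> "VerificationDataset":
        idx = self.verified_index
        if idx.size == 0:
            raise PVBDataError("no verified subjects")
        return VerificationDataset(self.t[idx], self.d[idx], self.v[idx])

    def to_frame(self) -> pd.DataFrame:
        d = self.d.astype(float)
        d[self.d == MISSING] = np.nan
        return pd.DataFrame({"test": self.t, "disease": d, "verified": self.v})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VerificationDataset":
        cols = {"test", "disease", "verified"}
        if not cols.issubset(frame.columns):
            raise PVBDataError(f"missing columns: {sorted(cols - set(frame.columns))}")
        return cls(
            frame["test"].to_numpy(),
            frame["disease"].to_numpy(dtype=float),
            frame["verified"].to_numpy(),
        )


@dataclass(frozen=True)
class CrossTable:
    """2x2 cross-classification of test result against disease status.

    Cells are reals so that inverse-probability-weighted counts reuse
    the same accuracy estimator as raw counts.
    """

    tp: float  # T=1, D=1
    fn: float  # T=0, D=1
    fp: float  # T=1, D=0
    tn: float  # T=0, D=0

    def __post_init__(self) -> None:
        cells = self.cells
        if np.any(cells < 0):
            raise PVBDataError(f"negative cell in cross table: {cells.tolist()}")
        if cells.sum() <= 0:
            raise PVBDataError("cross table has zero total")

    @property
    def cells(self) -> np.ndarray:
        return np.array([self.tp, self.fn, self.fp, self.tn], dtype=float)

    @property
    def total(self) -> float:
        return float(self.cells.sum())

    @property
    def valid(self) -> bool:
        """All four cells strictly positive (table dimension 4)."""
        return bool(np.all(self.cells > 0))


@dataclass(frozen=True)
class AccuracyEstimate:
    """Paired sensitivity/specificity point estimates.

    ``sn_interval``/``sp_interval`` hold (lower, upper) 95%-style bounds
    when an interval procedure has been applied.  ``flags`` records
    anomalies (e.g. a percentile interval that fails to contain the
    point estimate in a degenerate resample) instead of clamping them.
    """

    sn: float
    sp: float
    method: str = ""
    sn_interval: Optional[Tuple[float, float]] = None
    sp_interval: Optional[Tuple[float, float]] = None
    flags: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 <= self.sn <= 1.0) or not (0.0 <= self.sp <= 1.0):
            raise PVBDataError(
                f"accuracy estimates outside [0, 1]: sn={self.sn}, sp={self.sp}"
            )

    def with_intervals(self, sn_interval, sp_interval, flags=()) -> "AccuracyEstimate":
        return replace(
            self,
            sn_interval=tuple(sn_interval),
            sp_interval=tuple(sp_interval),
            flags=tuple(self.flags) + tuple(flags),
        )


def cell_ids(t: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Map (T, D) pairs to cell indices 0..3 in the order TP, FN, FP, TN."""
    # T=1,D=1 -> 0; T=0,D=1 -> 1; T=1,D=0 -> 2; T=0,D=0 -> 3
    return ((1 - np.asarray(t)) + 2 * (1 - np.asarray(d))).astype(np.intp)


def table_from_counts(counts: np.ndarray) -> CrossTable:
    c = np.asarray(counts, dtype=float)
    return CrossTable(c[0], c[1], c[2], c[3])


def cross_tabulate(data: VerificationDataset, verified_only: bool = False) -> CrossTable:
    """Cross-classify subjects by (T, D).

    With ``verified_only=True`` the tabulation is restricted to V=1
    subjects.  Otherwise the dataset must be complete; passing PVB data
    to a complete-data path is an error rather than a silent drop.
    """
    if verified_only:
        idx = data.verified_index
        if idx.size == 0:
            raise PVBDataError("no verified subjects to tabulate")
        t, d = data.t[idx], data.d[idx]
    else:
        if not data.is_complete:
            raise PVBDataError(
                f"dataset has {data.n0} unverified subjects with missing disease "
                "status; use verified_only=True or a PVB-aware estimator"
            )
        t, d = data.t, data.d
    counts = np.bincount(cell_ids(t, d), minlength=4)
    return table_from_counts(counts)


def estimate_accuracy(table: CrossTable, method: str = "") -> AccuracyEstimate:
    """Sn = TP/(TP+FN), Sp = TN/(FP+TN) from a (possibly weighted) table."""
    diseased = table.tp + table.fn
    nondiseased = table.fp + table.tn
    if diseased <= 0:
        raise PVBDataError("sensitivity undefined: no diseased subjects in table")
    if nondiseased <= 0:
        raise PVBDataError("specificity undefined: no non-diseased subjects in table")
    return AccuracyEstimate(
        sn=float(table.tp / diseased), sp=float(table.tn / nondiseased), method=method
    )
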