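"""CSV input/output and clinical-shaped fixture generation.

The on-disk schema is the analysis-ready clinical format: a comma-
separated, UTF-8 file with a header row and binary columns ``test``,
``disease``, ``verified``; the ``disease`` field is empty exactly when
``verified`` is 0.

Because the original clinical studies' cell counts are published only
as a figure, :func:`generate_fixture` builds *synthetic* stand-in
datasets whose margins (total size, verified count) match the published
ones exactly, with invented verified-stratum rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .data import PVBDataError, VerificationDataset

logger = logging.getLogger("pvbcorrect")


def read_clinical_csv(path) -> VerificationDataset:
    """Read and validate a subject-level PVB CSV.

    Raises :class:`PVBDataError` naming offending rows for unknown
    codings, a disease value on an unverified row, or missing columns.
    """
    frame = pd.read_csv(path)
    required = ["test", "disease", "verified"]
    missing_cols = [c for c in required if c not in frame.columns]
    if missing_cols:
        raise PVBDataError(f"{path}: missing columns {missing_cols}")
    for col in ("test", "verified"):
        vals = frame[col]
        bad = ~vals.isin([0, 1])
        if bad.any():
            rows = frame.index[bad][:5].tolist()
            raise PVBDataError(f"{path}: column {col!r} not in {{0,1}} at rows {rows}")
    disease = pd.to_numeric(frame["disease"], errors="coerce")
    coded = disease.notna()
    bad = coded & ~disease.isin([0, 1])
    if bad.any():
        rows = frame.index[bad][:5].tolist()
        raise PVBDataError(f"{path}: column 'disease' not in {{0,1,empty}} at rows {rows}")
    try:
        data = VerificationDataset(
            frame["test"].to_numpy(),
            disease.to_numpy(dtype=float),
            frame["verified"].to_numpy(),
        )
    except PVBDataError as exc:
        raise PVBDataError(f"{path}: {exc}") from exc
    logger.info(
        "read %s: n=%d, verified=%d (%.1f%% unverified)",
        path, data.n, data.n1, 100.0 * data.n0 / data.n,
    )
    return data


def write_clinical_csv(data: VerificationDataset, path) -> None:
    """Write a dataset in the clinical CSV schema (empty disease = missing)."""
    frame = data.to_frame()
    frame["disease"] = frame["disease"].map(lambda x: "" if pd.isna(x) else int(x))
    frame.to_csv(path, index=False)


@dataclass(frozen=True)
class FixtureProfile:
    """Exact margins for a synthetic clinical-shaped dataset.

    Verified subjects are specified per (T, D) cell; unverified
    subjects per T stratum.  Counts are materialised exactly (no
    sampling), only the row order is randomized.
    """

    name: str
    tp: int  # verified, T=1, D=1
    fn: int  # verified, T=0, D=1
    fp: int  # verified, T=1, D=0
    tn: int  # verified, T=0, D=0
    unverified_t1: int
    unverified_t0: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fn, self.fp, self.tn, self.unverified_t1, self.unverified_t0)
        if any(c < 0 for c in counts):
            raise ValueError(f"profile {self.name!r}: negative count in {counts}")
        if self.n_verified == 0:
            raise ValueError(f"profile {self.name!r}: no verified subjects")

    @property
    def n_verified(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n(self) -> int:
        return self.n_verified + self.unverified_t1 + self.unverified_t0


#: Synthetic stand-in for the hepatic-scintigraphy liver-cancer study
#: shape: 650 subjects, 344 verified by pathology (47.1% unverified).
#: Verified-cell rates are invented; only the margins are authentic.
SCINTIGRAPHY_LIKE = FixtureProfile(
    name="scintigraphy_like_synthetic",
    tp=231, fn=27, fp=32, tn=54,
    unverified_t1=61, unverified_t0=245,
)

#: Synthetic stand-in for the diaphanography breast-cancer study shape:
#: 900 subjects, only 88 verified by biopsy (90.2% unverified).
DIAPHANOGRAPHY_LIKE = FixtureProfile(
    name="diaphanography_like_synthetic",
    tp=26, fn=7, fp=11, tn=44,
    unverified_t1=9, unverified_t0=803,
)

PROFILES = {
    "scintigraphy": SCINTIGRAPHY_LIKE,
    "diaphanography": DIAPHANOGRAPHY_LIKE,
}


def generate_fixture(
    profile: Union[FixtureProfile, str],
    rng=None,
    path: Optional[str] = None,
) -> VerificationDataset:
    """Materialise a synthetic dataset with the profile's exact margins.

    Row order is shuffled with ``rng``; when ``path`` is given the
    dataset is also written as a clinical CSV.
    """
    if isinstance(profile, str):
        try:
            profile = PROFILES[profile]
        except KeyError:
            raise ValueError(
                f"unknown profile {profile!r}; choose from {sorted(PROFILES)}"
            ) from None
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    t = np.concatenate(
        [
            np.ones(profile.tp), np.zeros(profile.fn),
            np.ones(profile.fp), np.zeros(profile.tn),
            np.ones(profile.unverified_t1), np.zeros(profile.unverified_t0),
        ]
    )
    d = np.concatenate(
        [
            np.ones(profile.tp + profile.fn),
            np.zeros(profile.fp + profile.tn),
            np.full(profile.unverified_t1 + profile.unverified_t0, np.nan),
        ]
    )
    v = np.concatenate(
        [
            np.ones(profile.n_verified),
            np.zeros(profile.unverified_t1 + profile.unverified_t0),
        ]
    )
    order = rng.permutation(profile.n)
    data = VerificationDataset(t[order], d[order], v[order])
    if path is not None:
        write_clinical_csv(data, path)
    return data
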