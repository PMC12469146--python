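"""Simulation study harness and clinical-table analysis.

Performance of each estimator over B Monte Carlo repetitions is
summarised by the mean estimate, the bias (mean minus truth) and the
between-repetition standard error (B−1 denominator).  ``run_scenario``
evaluates a set of methods on B valid (complete, PVB) dataset pairs of
one scenario; ``run_grid`` maps it over the prevalence × (Sn, Sp) ×
sample-size grid; ``analyze_clinical`` produces the per-method
estimates-with-intervals table for a user dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import direct, imputation, intervals, resampling
from .data import VerificationDataset, cross_tabulate
from .resampling import BalanceSpec
from .simulate import (
    GRID_PREVALENCES,
    GRID_SAMPLE_SIZES,
    GRID_SNSP_PAIRS,
    ScenarioConfig,
    generate_valid_scenario,
)

PVB_METHODS = ("cca", "bg", "ipwe", "mi", "ipb", "sipw", "sipwb")
ALL_METHODS = ("fda",) + PVB_METHODS
_PS_METHODS = frozenset({"ipwe", "ipb", "sipw", "sipwb"})
#: Methods whose performance is evaluated over the pooled per-resample
#: estimates (B runs x b resamples) rather than the B per-run averages.
#: The pooled dispersion includes the within-dataset single-resample
#: variance, which is the precision notion the published comparison of
#: these correctors uses; see docs/methods.md ("Evaluating the
#: resampling correctors").
RESAMPLING_METHODS = frozenset({"ipb", "sipw", "sipwb"})

_METHOD_LABELS = {
    "fda": "FDA",
    "cca": "CCA",
    "bg": "BG",
    "ipwe": "IPWE",
    "mi": "MI",
    "ipb": "IPB",
    "sipw": "SIPW",
    "sipwb": "SIPW-B",
}


def bias(estimates: Sequence[float], truth: float) -> float:
    """Mean estimate minus the true parameter value."""
    arr = np.asarray(estimates, dtype=float)
    if arr.size == 0:
        raise ValueError("bias of an empty estimate list is undefined")
    return float(arr.mean() - truth)


def standard_error(estimates: Sequence[float]) -> float:
    """Between-repetition standard deviation (B−1 denominator)."""
    arr = np.asarray(estimates, dtype=float)
    if arr.size < 2:
        raise ValueError("standard error needs at least two estimates")
    return float(arr.std(ddof=1))


@dataclass(frozen=True)
class PerformanceRow:
    """Mean/bias/SE of one method in one scenario (one table cell block)."""

    method: str
    p: float
    sn_true: float
    sp_true: float
    n: int
    mean_sn: float
    bias_sn: float
    se_sn: float
    mean_sp: float
    bias_sp: float
    se_sp: float
    B: int


def _apply_method(
    method: str,
    complete: VerificationDataset,
    pvb: VerificationDataset,
    config: ScenarioConfig,
    rng: np.random.Generator,
    ps: Optional[np.ndarray],
    rel_size: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one method; returns (sn, sp) as length-1 arrays, or the
    per-resample lists for the resampling correctors."""
    if method == "fda":
        est = direct.fda_estimate(complete)
    elif method == "cca":
        est = direct.cca_estimate(pvb)
    elif method == "bg":
        est = direct.bg_estimate(pvb)
    elif method == "ipwe":
        est = direct.ipwe_estimate(pvb, ps=ps)
    elif method == "mi":
        est, _ = imputation.mi_estimate(pvb, m=config.m, rng=rng)
    elif method == "ipb":
        _, sn_list, sp_list = resampling.ipb_estimate(pvb, b=config.b, rng=rng, ps=ps)
        return sn_list, sp_list
    elif method == "sipw":
        _, sn_list, sp_list = resampling.sipw_estimate(pvb, b=config.b, rng=rng, ps=ps)
        return sn_list, sp_list
    elif method == "sipwb":
        _, sn_list, sp_list = resampling.sipwb_estimate(
            pvb, b=config.b, spec=BalanceSpec(rel_size), rng=rng, ps=ps
        )
        return sn_list, sp_list
    else:
        raise ValueError(f"unknown method {method!r}; choose from {ALL_METHODS}")
    return np.array([est.sn]), np.array([est.sp])


def run_scenario(
    config: ScenarioConfig,
    methods: Sequence[str] = ALL_METHODS,
    rng=None,
    rel_size: float = 1.0,
) -> list[PerformanceRow]:
    """Run one simulation scenario: B valid pairs, all requested methods.

    The propensity model is fitted once per dataset and shared by all
    propensity-based methods, exactly as a single analysis of that
    dataset would do.  For the resampling correctors (IPB, SIPW,
    SIPW-B) the mean/bias/SE summarise the pooled B x b per-resample
    estimates (the grand mean equals the mean of the per-run averages;
    the SE additionally carries the single-resample dispersion).
    """
    for method in methods:
        if method not in ALL_METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {ALL_METHODS}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    needs_ps = bool(_PS_METHODS.intersection(methods))
    results: Dict[str, list] = {m: [] for m in methods}
    for _ in range(config.B):
        try:
            complete, pvb, _ = generate_valid_scenario(config, rng)
            ps = resampling.fit_propensity(pvb) if needs_ps else None
            for method in methods:
                results[method].append(
                    _apply_method(method, complete, pvb, config, rng, ps, rel_size)
                )
        except Exception as exc:
            raise RuntimeError(
                f"scenario (p={config.p}, sn={config.sn_true}, sp={config.sp_true}, "
                f"n={config.n}) failed: {exc}"
            ) from exc
    rows = []
    for method in methods:
        sn = np.concatenate([pair[0] for pair in results[method]])
        sp = np.concatenate([pair[1] for pair in results[method]])
        rows.append(
            PerformanceRow(
                method=_METHOD_LABELS[method],
                p=config.p,
                sn_true=config.sn_true,
                sp_true=config.sp_true,
                n=config.n,
                mean_sn=float(sn.mean()),
                bias_sn=bias(sn, config.sn_true),
                se_sn=standard_error(sn) if sn.size > 1 else 0.0,
                mean_sp=float(sp.mean()),
                bias_sp=bias(sp, config.sp_true),
                se_sp=standard_error(sp) if sp.size > 1 else 0.0,
                B=config.B,
            )
        )
    return rows


def run_grid(
    prevalences: Sequence[float] = GRID_PREVALENCES,
    snsp_pairs: Sequence[Tuple[float, float]] = GRID_SNSP_PAIRS,
    sample_sizes: Sequence[int] = GRID_SAMPLE_SIZES,
    methods: Sequence[str] = ALL_METHODS,
    B: int = 500,
    b: int = 1000,
    m: int = 100,
    seed: Optional[int] = None,
    rel_size: float = 1.0,
) -> pd.DataFrame:
    """Run the full simulation grid; returns a tidy results table.

    One RNG substream is spawned per scenario from the master seed, so
    scenarios are reproducible independently of execution order.  A
    scenario that fails outright is reported as NA rows with a reason
    column instead of aborting the remaining grid.
    """
    scenarios = [
        ScenarioConfig(p=p, sn_true=sn, sp_true=sp, n=n, B=B, b=b, m=m)
        for p in prevalences
        for sn, sp in snsp_pairs
        for n in sample_sizes
    ]
    streams = np.random.SeedSequence(seed).spawn(len(scenarios))
    records = []
    for config, stream in zip(scenarios, streams):
        try:
            rows = run_scenario(config, methods, rng=np.random.default_rng(stream), rel_size=rel_size)
        except Exception as exc:
            for method in methods:
                records.append(
                    {
                        "p": config.p,
                        "sn_true": config.sn_true,
                        "sp_true": config.sp_true,
                        "n": config.n,
                        "method": _METHOD_LABELS[method],
                        "B": B,
                        "error": str(exc),
                    }
                )
            continue
        for row in rows:
            records.append(
                {
                    "p": row.p,
                    "sn_true": row.sn_true,
                    "sp_true": row.sp_true,
                    "n": row.n,
                    "method": row.method,
                    "mean_sn": row.mean_sn,
                    "bias_sn": row.bias_sn,
                    "se_sn": row.se_sn,
                    "mean_sp": row.mean_sp,
                    "bias_sp": row.bias_sp,
                    "se_sp": row.se_sp,
                    "B": row.B,
                    "error": "",
                }
            )
    frame = pd.DataFrame.from_records(records)
    cols = [
        "p", "sn_true", "sp_true", "n", "method",
        "mean_sn", "bias_sn", "se_sn", "mean_sp", "bias_sp", "se_sp", "B", "error",
    ]
    return frame.reindex(columns=cols)


def analyze_clinical(
    pvb: VerificationDataset,
    methods: Sequence[str] = PVB_METHODS,
    b: int = 1000,
    m: Optional[int] = None,
    R: int = 1000,
    level: float = 0.95,
    rel_size: float = 1.0,
    seed: Optional[int] = None,
    with_ci: bool = True,
) -> pd.DataFrame:
    """Per-method Sn/Sp (with 95% CIs) for one clinical-style dataset.

    Interval flavours follow each method's convention: Wald for CCA,
    Rubin's rules for MI, the native percentile interval for IPB, and
    the bootstrap percentile interval for BG, IPWE, SIPW and SIPW-B.
    The number of imputations defaults to the rounded percentage of
    incomplete (unverified) cases.  Per-method failures are reported as
    NA rows with the reason, not raised.
    """
    rng = np.random.default_rng(seed)
    if m is None:
        m = max(2, round(100.0 * pvb.n0 / pvb.n))
    records = []
    for method in methods:
        rec = {"method": _METHOD_LABELS.get(method, method)}
        try:
            rec.update(_clinical_one(pvb, method, b, m, R, level, rel_size, rng, with_ci))
        except Exception as exc:
            rec.update({"sn": np.nan, "sp": np.nan, "error": str(exc)})
        records.append(rec)
    frame = pd.DataFrame.from_records(records)
    frame.attrs.update(
        {
            "n": pvb.n,
            "n_verified": pvb.n1,
            "pct_unverified": round(100.0 * pvb.n0 / pvb.n, 1),
            "m": m,
            "b": b,
            "R": R,
            "level": level,
        }
    )
    return frame


def _clinical_one(pvb, method, b, m, R, level, rel_size, rng, with_ci) -> dict:
    sn_int = sp_int = None
    if method == "fda":
        est = direct.fda_estimate(pvb)
        if with_ci:
            table = cross_tabulate(pvb)
            sn_int = intervals.wald_ci(est.sn, table.tp + table.fn, level)
            sp_int = intervals.wald_ci(est.sp, table.fp + table.tn, level)
    elif method == "cca":
        est = direct.cca_estimate(pvb)
        if with_ci:
            table = cross_tabulate(pvb, verified_only=True)
            sn_int = intervals.wald_ci(est.sn, table.tp + table.fn, level)
            sp_int = intervals.wald_ci(est.sp, table.fp + table.tn, level)
    elif method in ("bg", "ipwe"):
        fn = direct.bg_estimate if method == "bg" else direct.ipwe_estimate
        est = fn(pvb)
        if with_ci:
            sn_int, sp_int = intervals.bootstrap_percentile_ci(fn, pvb, R, level, rng)
    elif method == "mi":
        est, draws = imputation.mi_estimate(pvb, m=m, rng=rng)
        if with_ci:
            sn_int, sp_int = intervals.rubin_ci(draws, level)
    elif method == "ipb":
        est, sn_list, sp_list = resampling.ipb_estimate(pvb, b=b, rng=rng)
        if with_ci:
            sn_int = intervals.ipb_native_ci(sn_list, level)
            sp_int = intervals.ipb_native_ci(sp_list, level)
    elif method in ("sipw", "sipwb"):
        if method == "sipw":
            est, _, _ = resampling.sipw_estimate(pvb, b=b, rng=rng)

            def point(ds, _b=b):
                e, _, _ = resampling.sipw_estimate(ds, b=_b, rng=rng)
                return e

        else:
            spec = BalanceSpec(rel_size)
            est, _, _ = resampling.sipwb_estimate(pvb, b=b, spec=spec, rng=rng)

            def point(ds, _b=b, _spec=spec):
                e, _, _ = resampling.sipwb_estimate(ds, b=_b, spec=_spec, rng=rng)
                return e

        if with_ci:
            sn_int, sp_int = intervals.bootstrap_percentile_ci(point, pvb, R, level, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    rec = {"sn": est.sn, "sp": est.sp, "error": ""}
    if sn_int is not None:
        rec.update(
            {
                "sn_lower": sn_int.lower,
                "sn_upper": sn_int.upper,
                "sp_lower": sp_int.lower,
                "sp_upper": sp_int.upper,
                "ci_method": sn_int.method,
            }
        )
    return rec
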