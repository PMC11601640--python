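"""Non-compartmental pharmacokinetic analysis.

AUC0-t by the linear trapezoidal rule; terminal rate constant by log-linear
OLS over an automatically selected tail (best adjusted r^2 over suffixes of
length >= 3 after Tmax); AUC0-inf = AUC0-t + C_last / lambda; half-life
t1/2 = 0.693 / lambda.  The constant 0.693 is used verbatim rather than
ln 2 to match the reported formula (a 0.015% difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HALF_LIFE_CONSTANT = 0.693


@dataclass
class NCAResult:
    analyte: str = ""
    matrix: str = ""
    cmax: float = np.nan
    tmax: float = np.nan
    auc_0_t: float = np.nan
    auc_0_inf: float = np.nan
    lambda_z: float = np.nan
    half_life: float = np.nan
    n_lambda: int = 0
    r_squared: float = np.nan
    pct_extrapolated: float = np.nan
    flags: str = ""


def auc_trapezoid(times: np.ndarray, concentrations: np.ndarray) -> float:
    """Linear trapezoidal AUC over strictly increasing times."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size != c.size or t.size < 2:
        raise ValueError("need >= 2 matched (time, concentration) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.sum(np.diff(t) * (c[:-1] + c[1:]) / 2.0))


def _ols_loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """(slope, r^2) of ln(c) on t."""
    y = np.log(c)
    n = t.size
    tm, ym = t.mean(), y.mean()
    sxx = np.sum((t - tm) ** 2)
    sxy = np.sum((t - tm) * (y - ym))
    slope = sxy / sxx
    yhat = ym + slope * (t - tm)
    sse = np.sum((y - yhat) ** 2)
    sst = np.sum((y - ym) ** 2)
    r2 = 1.0 if sst == 0 and sse == 0 else (1.0 - sse / sst if sst > 0 else 0.0)
    return float(slope), float(r2)


def terminal_lambda(
    times: np.ndarray,
    concentrations: np.ndarray,
    tail: int | None = None,
    min_points: int = 3,
) -> tuple[float, int, float]:
    """Terminal rate constant by log-linear regression.

    Returns (lambda, n points, r^2); NaN lambda when < ``min_points`` usable
    points or when the fitted slope is >= 0 (flagged not-reportable).  The
    tail is user-specified (last ``tail`` points) or auto-selected as the
    suffix (length >= min_points, starting after Tmax) with the best adjusted
    r^2.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    keep = np.isfinite(c) & (c > 0)
    t, c = t[keep], c[keep]
    if t.size < min_points:
        return np.nan, 0, np.nan
    if tail is not None:
        if tail < min_points or tail > t.size:
            raise ValueError("invalid tail length")
        tt, cc = t[-tail:], c[-tail:]
        slope, r2 = _ols_loglinear(tt, cc)
        n = tail
    else:
        i_tmax = int(np.argmax(c))
        start_min = i_tmax + 1  # exclude Tmax itself
        best = None
        for start in range(start_min, t.size - min_points + 1):
            tt, cc = t[start:], c[start:]
            slope, r2 = _ols_loglinear(tt, cc)
            n = tt.size
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
            if best is None or adj > best[0] + 1e-12:
                best = (adj, slope, r2, n)
        if best is None:
            # profile too short after Tmax; fall back to the last min_points
            tt, cc = t[-min_points:], c[-min_points:]
            slope, r2 = _ols_loglinear(tt, cc)
            n = min_points
        else:
            _, slope, r2, n = best
    lam = -slope
    if lam <= 0:
        return np.nan, int(n), float(r2)
    return float(lam), int(n), float(r2)


def auc_extrapolate(auc0t: float, c_last: float, lambda_z: float) -> tuple[float, float]:
    """AUC0-inf = AUC0-t + C_last/lambda; returns (AUC0-inf, % extrapolated)."""
    if not np.isfinite(lambda_z) or lambda_z <= 0:
        return np.nan, np.nan
    if c_last < 0:
        raise ValueError("c_last must be >= 0")
    auc_inf = auc0t + c_last / lambda_z
    pct = 100.0 * (auc_inf - auc0t) / auc_inf if auc_inf > 0 else 0.0
    return float(auc_inf), float(pct)


def half_life(lambda_z: float) -> float:
    """t1/2 = 0.693 / lambda (NaN when lambda is not reportable)."""
    if not np.isfinite(lambda_z) or lambda_z <= 0:
        return np.nan
    return HALF_LIFE_CONSTANT / lambda_z


def summarize_nca(
    profile: pd.DataFrame,
    lloq_policy: str = "standard",
    tail: int | None = None,
) -> list[NCAResult]:
    """NCA per analyte x matrix from a long observation table.

    Columns: analyte, matrix, animal, time_h, conc, lloq_flag (optional).
    Concentrations are averaged across animals per nominal time (naive
    pooling, destructive sampling design).  LLOQ policy ``standard``: mean
    values flagged below LLOQ are set to 0 before Tmax and excluded after
    Tmax (AUC then ends at the last quantifiable point); ``keep`` uses all
    values as-is.
    """
    if lloq_policy not in ("standard", "keep"):
        raise ValueError("lloq_policy must be 'standard' or 'keep'")
    results = []
    for (analyte, matrix), grp in profile.groupby(["analyte", "matrix"]):
        agg = grp.groupby("time_h").agg(
            conc=("conc", "mean"),
            blq=("lloq_flag", "all") if "lloq_flag" in grp else ("conc", lambda v: False),
        )
        agg = agg.sort_index()
        t = agg.index.to_numpy(dtype=float)
        c = agg["conc"].to_numpy(dtype=float)
        blq = agg["blq"].to_numpy(dtype=bool)
        res = NCAResult(analyte=analyte, matrix=matrix)
        if lloq_policy == "standard":
            if np.all(blq):
                res.flags = "all observations below LLOQ"
                results.append(res)
                continue
            i_tmax = int(np.argmax(np.where(blq, -np.inf, c)))
            pre = blq & (np.arange(len(t)) < i_tmax)
            c = np.where(pre, 0.0, c)
            keep = ~(blq & (np.arange(len(t)) > i_tmax))
            t, c = t[keep], c[keep]
        if t.size == 0:
            res.flags = "no usable observations"
            results.append(res)
            continue
        i_tmax = int(np.argmax(c))
        res.cmax = float(c[i_tmax])
        res.tmax = float(t[i_tmax])
        if t.size >= 2:
            res.auc_0_t = auc_trapezoid(t, c)
        lam, n, r2 = terminal_lambda(t, c, tail=tail)
        res.lambda_z, res.n_lambda, res.r_squared = lam, n, r2
        if np.isfinite(lam):
            res.auc_0_inf, res.pct_extrapolated = auc_extrapolate(res.auc_0_t, c[-1], lam)
            res.half_life = half_life(lam)
        else:
            res.flags = "terminal slope not reportable"
        results.append(res)
    return results


def nca_report(results: list[NCAResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
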