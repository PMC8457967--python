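"""Environmental aggregation, the temperature-humidity index and Kendall
rank correlation.

Sensor streams (ammonia in ppm, air temperature in deg C, relative
humidity in %) are averaged per clock-hour analysis period.  Heat load is
summarised by the temperature-humidity index

    THI = 1.8 T + 32 - (0.55 - 0.0055 RH) (1.8 T - 26),

computed on the period-mean T and RH.  Associations between THI, ammonia
and activity are measured with Kendall's rank correlation: tau-a is the
plain concordance ratio

    tau_a = sum_{i != j} sgn(x_i - x_j) sgn(y_i - y_j) / (n (n - 1)),

and tau-b divides C - D by the tie-corrected pair counts.  Two-sided
p-values come from exact enumeration of rank arrangements (small
tie-free samples), from the normal approximation with the tie-corrected
variance of S = C - D, or from seeded permutation resampling when an
exact value is requested but infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan

import numpy as np
import pandas as pd

__all__ = [
    "PERIODS",
    "PeriodSummary",
    "CorrelationResult",
    "compute_thi",
    "aggregate_periods",
    "kendall_tau",
    "kendall_pvalue",
    "correlate_periods",
    "read_sensor_csv",
    "summaries_to_frame",
    "frame_to_summaries",
]

#: Default analysis periods: clock-hour windows starting at these hours.
PERIODS = (6, 12, 18)


def period_label(start_hour: int) -> str:
    return f"{start_hour:02d}:00-{start_hour:02d}:59"


@dataclass
class PeriodSummary:
    """Per (date, period) means of the sensor fields plus THI and activity."""

    date: str
    period: str
    mean_nh3: float = float("nan")
    mean_temp: float = float("nan")
    mean_rh: float = float("nan")
    thi: float = float("nan")
    activity: float = float("nan")
    complete: bool = True


@dataclass
class CorrelationResult:
    tau: float
    variant: str
    p_value: float
    n: int
    method: str = ""
    # paired series retained so p-value methods can be re-run on the result
    x: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)


def compute_thi(temp: float, rh: float) -> float:
    """Temperature-humidity index from air temperature (deg C) and RH (%).

    At RH = 100 the humidity term vanishes and THI is the plain
    Fahrenheit conversion 1.8 T + 32; at T = 130/9 deg C (where
    1.8 T - 26 = 0) THI is 58 for any humidity.
    """
    temp = np.asarray(temp, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    thi = 1.8 * temp + 32 - (0.55 - 0.0055 * rh) * (1.8 * temp - 26)
    return float(thi) if thi.ndim == 0 else thi


def read_sensor_csv(path) -> pd.DataFrame:
    """Read a sensor CSV (`timestamp,nh3_ppm,temp_c,rh_pct`; empty = missing)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    for col in ("nh3_ppm", "temp_c", "rh_pct"):
        if col not in df.columns:
            raise ValueError(f"sensor CSV missing column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def aggregate_periods(readings: pd.DataFrame, periods=PERIODS) -> list[PeriodSummary]:
    """Average sensor readings into per-(date, period) summaries.

    Windows are half-open clock hours [start, start+1h).  A (date,
    period) with no reading for any of the three fields is dropped,
    mirroring a completeness rule: analyse only periods where the record
    is complete.
    """
    if len(readings) == 0:
        return []
    df = readings.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["date"] = ts.dt.strftime("%Y-%m-%d")
    df["hour"] = ts.dt.hour
    out: list[PeriodSummary] = []
    for (date, hour), grp in df.groupby(["date", "hour"], sort=True):
        if hour not in periods:
            continue
        means = {c: grp[c].mean() for c in ("nh3_ppm", "temp_c", "rh_pct")}
        if any(isnan(v) for v in means.values()):
            continue
        out.append(
            PeriodSummary(
                date=date,
                period=period_label(int(hour)),
                mean_nh3=float(means["nh3_ppm"]),
                mean_temp=float(means["temp_c"]),
                mean_rh=float(means["rh_pct"]),
                thi=compute_thi(means["temp_c"], means["rh_pct"]),
            )
        )
    return out


# ---------------------------------------------------------------- Kendall


def _concordance(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """S = C - D and the tie-corrected pair counts (n0, n1, n2)."""
    n = x.size
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    s = float((sx * sy).sum()) / 2.0  # each unordered pair counted twice
    n0 = n * (n - 1) / 2.0
    _, tx = np.unique(x, return_counts=True)
    _, ty = np.unique(y, return_counts=True)
    n1 = float((tx * (tx - 1) / 2.0).sum())
    n2 = float((ty * (ty - 1) / 2.0).sum())
    return s, n0, n1, n2


def kendall_tau(x, y, variant: str = "tau_b") -> CorrelationResult:
    """Kendall rank correlation of two paired series.

    ``tau_a`` is the concordance sum over all ordered pairs divided by
    n(n-1); ``tau_b`` applies the standard tie correction.  The returned
    result carries the data so p-values can be attached with
    :func:`kendall_pvalue`; its ``p_value`` field is pre-filled with the
    normal approximation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    if variant not in ("tau_a", "tau_b"):
        raise ValueError(f"unknown variant {variant!r}")
    s, n0, n1, n2 = _concordance(x, y)
    if variant == "tau_a":
        tau = s / n0
    else:
        denom = np.sqrt((n0 - n1) * (n0 - n2))
        tau = s / denom if denom > 0 else float("nan")
    res = CorrelationResult(tau=float(tau), variant=variant, p_value=float("nan"),
                            n=int(x.size), x=x, y=y)
    res.p_value = kendall_pvalue(res, method="normal_approx")
    res.method = "normal_approx"
    return res


def _exact_pvalue_enumeration(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by full enumeration of the n! arrangements of y."""
    from itertools import permutations

    n = x.size
    s_obs, *_ = _concordance(x, y)
    total = 0
    at_least = 0
    for perm in permutations(range(n)):
        s, *_ = _concordance(x, y[list(perm)])
        total += 1
        if abs(s) >= abs(s_obs) - 1e-12:
            at_least += 1
    return at_least / total


def _permutation_pvalue(x: np.ndarray, y: np.ndarray, n_resamples: int,
                        seed: int) -> float:
    rng = np.random.default_rng(seed)
    s_obs, *_ = _concordance(x, y)
    count = 0
    for _ in range(n_resamples):
        s, *_ = _concordance(x, rng.permutation(y))
        if abs(s) >= abs(s_obs) - 1e-12:
            count += 1
    return (count + 1) / (n_resamples + 1)


def kendall_pvalue(result: CorrelationResult, method: str = "normal_approx",
                   n_resamples: int = 100_000, seed: int = 0) -> float:
    """Two-sided p-value for a Kendall correlation result.

    ``exact`` enumerates all rank arrangements (feasible for n <= 10 and
    no ties); otherwise it falls back to seeded permutation resampling
    with ``n_resamples`` draws and flags the result's ``method`` field.
    ``normal_approx`` uses the tie-corrected variance of S = C - D.
    """
    x, y = result.x, result.y
    if x is None or y is None:
        raise ValueError("result does not carry its data; recompute with kendall_tau")
    n = result.n
    if method == "exact":
        has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
        if n <= 8 and not has_ties:
            result.method = "exact"
            return _exact_pvalue_enumeration(x, y)
        if n <= 10 and not has_ties:
            # tie-free: the null distribution of S depends on ranks only;
            # scipy's exact method enumerates it efficiently
            from scipy import stats

            result.method = "exact"
            return float(stats.kendalltau(x, y, method="exact").pvalue)
        result.method = "permutation"
        return _permutation_pvalue(x, y, max(n_resamples, 100_000), seed)
    if method == "normal_approx":
        from scipy import stats

        result.method = "normal_approx"
        if n < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
            return float("nan")  # no rank information / approximation undefined
        return float(stats.kendalltau(x, y, method="asymptotic").pvalue)
    raise ValueError(f"unknown p-value method {method!r}")


def correlate_periods(summaries, var_x: str, var_y: str,
                      variant: str = "tau_b") -> CorrelationResult:
    """Kendall correlation between two per-period variables.

    Summaries are ordered by (date, period); periods where either
    variable is missing are dropped listwise.
    """
    rows = sorted(summaries, key=lambda s: (s.date, s.period))
    xs, ys = [], []
    for s in rows:
        vx = getattr(s, var_x)
        vy = getattr(s, var_y)
        if isnan(vx) or isnan(vy):
            continue
        xs.append(vx)
        ys.append(vy)
    if len(xs) < 2:
        raise ValueError("need at least two complete (var_x, var_y) pairs")
    return kendall_tau(xs, ys, variant=variant)


# ------------------------------------------------------------- CSV round-trip

_SUMMARY_COLS = ["date", "period", "mean_nh3", "mean_temp", "mean_rh", "thi",
                 "activity", "complete"]


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(s, c) for c in _SUMMARY_COLS} for s in summaries],
                        columns=_SUMMARY_COLS)


def frame_to_summaries(df: pd.DataFrame) -> list[PeriodSummary]:
    out = []
    for _, row in df.iterrows():
        out.append(PeriodSummary(
            date=str(row["date"]),
            period=str(row["period"]),
            mean_nh3=float(row.get("mean_nh3", float("nan"))),
            mean_temp=float(row.get("mean_temp", float("nan"))),
            mean_rh=float(row.get("mean_rh", float("nan"))),
            thi=float(row.get("thi", float("nan"))),
            activity=float(row.get("activity", float("nan"))),
            complete=bool(row.get("complete", True)),
        ))
    return out
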