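"""Lap-to-lap reliability: variance-mean analysis with power-law fits.

For each cell, the per-lap activity rate in each 2-cm bin gives, across
laps, a mean and a variance per spatial bin. The relation between them is
summarized by fitting y = a * x^beta with total least squares (TLS) in
log-log space; beta = 1 is the signature of Poisson-like reliability, and
larger exponents indicate extra lap-to-lap variability. TLS is used because
both the mean and the variance are estimated, so the orthogonal residual is
the natural loss (ordinary least squares on y|x attenuates the slope).

Also provides activity-rate summaries: event rates are reported as mean +/-
s.e.m., while activity rates (approximately log-normal across cells) are
reported with a 90% confidence interval of the mean computed on the log
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import AlignedSession
from .errors import InsufficientDataError
from .ratemap import LapRateMatrix

# ---------------------------------------------------------------------------
# Variance-mean relation
# ---------------------------------------------------------------------------

def variance_mean_relation(
    lapmat: LapRateMatrix, min_laps: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Across-lap mean and unbiased variance of the per-lap rate, per bin.

    Only laps that visited a bin contribute to that bin; bins visited in
    fewer than ``min_laps`` laps are dropped (variance undefined).
    """
    if lapmat.n_laps < 2:
        raise InsufficientDataError("need at least two laps")
    r = lapmat.rate
    n_visits = np.sum(np.isfinite(r), axis=0)
    keep = n_visits >= min_laps
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(r[:, keep], axis=0)
        var = np.nanvar(r[:, keep], axis=0, ddof=1)
    return mean, var


# ---------------------------------------------------------------------------
# Total least squares power-law fit
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    a: float
    beta: float
    residual: float       # RMS orthogonal distance in log-log space
    n_points: int


def fit_power_law_tls(mean: np.ndarray, var: np.ndarray) -> PowerLawFit:
    """Fit y = a * x^beta by total least squares in log-log space.

    The fitted line is the first principal direction of the centered
    (log mean, log var) scatter; beta is its slope and a = exp(intercept).
    Points with non-positive mean or variance are excluded before the log
    transform.
    """
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    ok = np.isfinite(mean) & np.isfinite(var) & (mean > 0) & (var > 0)
    x = np.log(mean[ok])
    y = np.log(var[ok])
    if x.size < 3:
        raise InsufficientDataError("need at least 3 positive (mean, var) points")
    pts = np.column_stack([x, y])
    center = pts.mean(axis=0)
    centered = pts - center
    if np.allclose(centered, 0):
        raise InsufficientDataError("zero spread in (mean, var) points")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction[0] == 0:
        raise InsufficientDataError("vertical principal direction; slope undefined")
    if direction[0] < 0:
        direction = -direction
    beta = float(direction[1] / direction[0])
    intercept = float(center[1] - beta * center[0])
    normal = np.array([-direction[1], direction[0]])
    resid = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PowerLawFit(a=float(np.exp(intercept)), beta=beta, residual=resid,
                       n_points=int(x.size))


def fit_cell_exponent(lapmat: LapRateMatrix) -> PowerLawFit:
    """Variance-mean points and TLS power-law fit for one cell."""
    mean, var = variance_mean_relation(lapmat)
    return fit_power_law_tls(mean, var)


def reliability_table(
    session: AlignedSession,
    is_place_cell: np.ndarray,
    params=None,
) -> pd.DataFrame:
    """Per-cell export: group, rates and power-law fit (NaN where the fit
    is undefined). Columns: cell, group, event_rate, activity_rate, a,
    beta, n_points."""
    from .ratemap import per_lap_maps

    df = cell_rates(session)
    df["group"] = np.where(np.asarray(is_place_cell, bool), "place",
                           "non_place")
    laps = session.laps()
    a = np.full(session.n_cells, np.nan)
    beta = np.full(session.n_cells, np.nan)
    n_points = np.zeros(session.n_cells, dtype=int)
    for cell in range(session.n_cells):
        try:
            fit = fit_cell_exponent(per_lap_maps(session, cell, laps, params))
        except InsufficientDataError:
            continue
        a[cell], beta[cell], n_points[cell] = fit.a, fit.beta, fit.n_points
    df["a"] = a
    df["beta"] = beta
    df["n_points"] = n_points
    return df[["cell", "group", "event_rate", "activity_rate", "a", "beta",
               "n_points"]]


# ---------------------------------------------------------------------------
# Rate summaries
# ---------------------------------------------------------------------------

def lognormal_mean_ci(
    values: np.ndarray, level: float = 0.90
) -> tuple[float, float]:
    """Cox confidence interval for the mean of a log-normal sample.

    Computed on the log scale: exp(m + s^2/2 +/- z * sqrt(s^2/n +
    s^4/(2(n-1)))) with m, s^2 the sample moments of log(values).
    """
    from scipy.stats import norm

    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    n = values.size
    if n < 2:
        raise InsufficientDataError("need at least two positive values")
    logs = np.log(values)
    s2 = logs.var(ddof=1)
    center = logs.mean() + s2 / 2.0
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(s2 / n + s2 ** 2 / (2.0 * (n - 1)))
    return float(np.exp(center - half)), float(np.exp(center + half))


@dataclass
class RateSummary:
    per_cell: pd.DataFrame
    group_event_rate: pd.DataFrame     # mean, sem per group
    group_activity_rate: pd.DataFrame  # mean, 90% CI (log-scale) per group


def cell_rates(session: AlignedSession) -> pd.DataFrame:
    """Per-cell event rate (events/s) and activity rate (dF/F/s) over moving
    frames."""
    moving = session.moving
    t_moving = moving.sum() / session.frame_rate
    if t_moving == 0:
        raise InsufficientDataError("no moving time")
    acts = session.activity[moving]
    return pd.DataFrame({
        "cell": np.arange(session.n_cells),
        "event_rate": np.sum(acts > 0, axis=0) / t_moving,
        "activity_rate": acts.sum(axis=0) / t_moving,
    })


def rate_summary(
    session: AlignedSession,
    is_place_cell: np.ndarray,
    ci_level: float = 0.90,
) -> RateSummary:
    """Group rate summaries for place vs non-place cells.

    Event rates use mean +/- s.e.m.; activity rates use Cox's log-scale
    confidence interval for the mean of a log-normal distribution,
    exp(m + s^2/2 +/- z * sqrt(s^2/n + s^4 / (2(n-1)))) with m, s^2 the
    moments of the log rates (zero-rate cells are excluded from the
    log-scale interval).
    """
    df = cell_rates(session)
    df["group"] = np.where(np.asarray(is_place_cell, bool), "place", "non_place")
    ev_rows, act_rows = [], []
    for g, sub in df.groupby("group"):
        ev = sub["event_rate"].to_numpy()
        ev_rows.append({
            "group": g, "n": ev.size, "mean": ev.mean(),
            "sem": ev.std(ddof=1) / np.sqrt(ev.size) if ev.size > 1 else np.nan,
        })
        act = sub["activity_rate"].to_numpy()
        act = act[act > 0]
        try:
            lo, hi = lognormal_mean_ci(act, ci_level)
        except InsufficientDataError:
            lo = hi = np.nan
        act_rows.append({
            "group": g, "n": act.size, "mean": sub["activity_rate"].mean(),
            "ci_low": lo, "ci_high": hi, "ci_level": ci_level,
        })
    return RateSummary(
        per_cell=df,
        group_event_rate=pd.DataFrame(ev_rows),
        group_activity_rate=pd.DataFrame(act_rows),
    )
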