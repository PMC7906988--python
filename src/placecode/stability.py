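"""Cross-session and cross-environment statistics.

Recurrence (fraction of cells holding a classification on day 0 that hold it
again N days later), place-field correlation (mean Pearson correlation of the
normalized smoothed rate maps of recurring place cells), circular field shift,
and the Hodges-Ajne nonparametric test of circular uniformity applied to
field-shift distributions (the signature of global remapping is a uniform
shift distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import pearsonr

from .behavior import AlignedSession
from .config import AnalysisParams
from .errors import InsufficientDataError
from .placecell import classify_population, rate_map_1d, rate_map_2d

# ---------------------------------------------------------------------------
# Per-session results container
# ---------------------------------------------------------------------------

@dataclass
class SessionResult:
    """Classification table plus normalized smoothed maps for one session.

    ``maps`` is cells x bins (2D maps flattened), NaN where invalid, so that
    map correlations across sessions use only jointly valid bins. Sessions
    compared pairwise must share a registered cell index.
    """

    stats: pd.DataFrame
    maps: np.ndarray
    environment: str
    day: int
    circumference_cm: float | None = None

    @property
    def active(self) -> np.ndarray:
        return self.stats["n_events"].to_numpy() > 0

    @property
    def place(self) -> np.ndarray:
        return self.stats["is_place_cell"].to_numpy().astype(bool)

    @property
    def field_location_cm(self) -> np.ndarray:
        return self.stats["field_location_cm"].to_numpy(dtype=float)


def analyze_session(
    session: AlignedSession,
    params: AnalysisParams | None = None,
    seed: int | np.random.Generator | None = 0,
) -> SessionResult:
    """Classify all cells and collect their normalized smoothed maps."""
    params = params or AnalysisParams()
    stats, _ = classify_population(session, params, seed)
    maps = []
    for cell in range(session.n_cells):
        try:
            if session.arena == "circular_track":
                rm = rate_map_1d(session, cell, params)
                maps.append(rm.normalized_rate)
            else:
                rm = rate_map_2d(session, cell, params)
                maps.append(rm.normalized_rate.ravel())
        except Exception:
            maps.append(None)
    n_bins = next(len(m) for m in maps if m is not None)
    maps = np.vstack([
        m if m is not None else np.full(n_bins, np.nan) for m in maps
    ])
    return SessionResult(
        stats=stats,
        maps=maps,
        environment=session.environment,
        day=session.day,
        circumference_cm=session.circumference_cm,
    )


# ---------------------------------------------------------------------------
# Circular helpers
# ---------------------------------------------------------------------------

def circular_shift_cm(a_cm: float, b_cm: float, circumference_cm: float) -> float:
    """Signed circular difference b - a, wrapped to (-C/2, C/2]."""
    d = (b_cm - a_cm) % circumference_cm
    if d > circumference_cm / 2.0:
        d -= circumference_cm
    return float(d)


def _map_correlation(ma: np.ndarray, mb: np.ndarray) -> float:
    ok = np.isfinite(ma) & np.isfinite(mb)
    if ok.sum() < 3 or np.std(ma[ok]) == 0 or np.std(mb[ok]) == 0:
        return np.nan
    return float(pearsonr(ma[ok], mb[ok])[0])


# ---------------------------------------------------------------------------
# Hodges-Ajne test
# ---------------------------------------------------------------------------

def hodges_ajne_test(angles_deg: np.ndarray) -> tuple[int, float]:
    """Hodges-Ajne test of circular uniformity.

    The statistic m is the minimum number of points contained in any closed
    half-circle; small m means the sample is concentrated on one side. For
    m < n/3 the exact tail probability is

        p = (n - 2m) * C(n, m) * 2^(1-n),

    otherwise the asymptotic approximation of Ajne's A statistic is used.
    Returns (m, p) with p clipped to [0, 1].
    """
    angles = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    n = angles.size
    if n < 4:
        raise InsufficientDataError("Hodges-Ajne test needs n >= 4")
    m = _min_halfcircle_count(angles)
    if n - 2 * m == 0:
        return m, 1.0
    if m < n / 3.0:
        p = (n - 2 * m) * comb(n, m, exact=True) * 2.0 ** (1 - n)
    else:
        big_a = np.pi * np.sqrt(n) / (2.0 * (n - 2 * m))
        p = np.sqrt(2.0 * np.pi) / big_a * np.exp(-np.pi ** 2 / (8 * big_a ** 2))
    return m, float(np.clip(p, 0.0, 1.0))


def _min_halfcircle_count(angles: np.ndarray) -> int:
    """Minimum count over all closed half-circles [a, a + 180].

    The count function is piecewise constant with breakpoints where a data
    angle or its antipode crosses a boundary, so evaluating at each data
    angle, its antipode, and just past each suffices.
    """
    eps = 1e-9
    anchors = np.concatenate([
        angles, angles + 180.0, angles + eps, angles + 180.0 + eps
    ]) % 360.0
    rel = (angles[None, :] - anchors[:, None]) % 360.0
    counts = np.sum(rel <= 180.0, axis=1)
    return int(counts.min())


# ---------------------------------------------------------------------------
# Session-pair statistics (stability over days)
# ---------------------------------------------------------------------------

@dataclass
class SessionPairStats:
    day_interval: int
    recurrence_active: float
    recurrence_place: float
    field_correlation: float          # NaN when no recurring place cells
    field_shifts_cm: np.ndarray       # per recurring place cell
    mean_map_correlation_all_cells: float
    n_place_a: int
    n_recurring_place: int


def session_pair_stats(a: SessionResult, b: SessionResult) -> SessionPairStats:
    """Recurrence, field correlation and field shift for a pair of sessions.

    Recurrence is directional (a -> b): the fraction of cells classified in
    session a that retain the classification in session b. Correlations use
    normalized smoothed maps restricted to bins valid in both sessions.
    """
    if len(a.stats) != len(b.stats):
        raise InsufficientDataError("sessions do not share a registered cell index")
    active_a, active_b = a.active, b.active
    place_a, place_b = a.place, b.place
    rec_active = (
        float(np.sum(active_a & active_b) / np.sum(active_a))
        if active_a.any() else np.nan
    )
    rec_place = (
        float(np.sum(place_a & place_b) / np.sum(place_a))
        if place_a.any() else np.nan
    )
    recurring = place_a & place_b
    corrs = [
        _map_correlation(a.maps[i], b.maps[i]) for i in np.nonzero(recurring)[0]
    ]
    field_corr = float(np.nanmean(corrs)) if corrs else np.nan
    shifts = []
    if a.circumference_cm is not None:
        la, lb = a.field_location_cm, b.field_location_cm
        for i in np.nonzero(recurring)[0]:
            if np.isfinite(la[i]) and np.isfinite(lb[i]):
                shifts.append(circular_shift_cm(la[i], lb[i], a.circumference_cm))
    both_active = active_a & active_b
    all_corrs = [
        _map_correlation(a.maps[i], b.maps[i]) for i in np.nonzero(both_active)[0]
    ]
    return SessionPairStats(
        day_interval=b.day - a.day,
        recurrence_active=rec_active,
        recurrence_place=rec_place,
        field_correlation=field_corr,
        field_shifts_cm=np.asarray(shifts),
        mean_map_correlation_all_cells=(
            float(np.nanmean(all_corrs)) if all_corrs else np.nan
        ),
        n_place_a=int(place_a.sum()),
        n_recurring_place=int(recurring.sum()),
    )


def pairwise_stats_table(results: list[SessionResult]) -> pd.DataFrame:
    """Pool all session pairs, keyed by day interval (forward pairs only)."""
    rows = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            st = session_pair_stats(results[i], results[j])
            rows.append({
                "session_a": i,
                "session_b": j,
                "day_interval": st.day_interval,
                "recurrence_active": st.recurrence_active,
                "recurrence_place": st.recurrence_place,
                "field_correlation": st.field_correlation,
                "mean_map_correlation_all_cells": st.mean_map_correlation_all_cells,
                "n_recurring_place": st.n_recurring_place,
            })
    return pd.DataFrame(rows)


def shift_table(results: list[SessionResult]) -> pd.DataFrame:
    """Long-format field-shift distributions over all forward session
    pairs: one row per recurring place cell per pair."""
    rows = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            st = session_pair_stats(results[i], results[j])
            for shift in st.field_shifts_cm:
                rows.append({
                    "session_a": i, "session_b": j,
                    "day_interval": st.day_interval, "shift_cm": shift,
                })
    return pd.DataFrame(rows, columns=["session_a", "session_b",
                                       "day_interval", "shift_cm"])


# ---------------------------------------------------------------------------
# Cross-environment remapping
# ---------------------------------------------------------------------------

@dataclass
class RemapStats:
    n_common_active: int
    n_common_place_cells: int
    fraction_retaining_location: float
    mean_activity_correlation: float
    shift_distribution_cm: np.ndarray
    hodges_ajne_m: int | None
    hodges_ajne_p: float


def cross_track_remapping(
    a: SessionResult,
    b: SessionResult,
    params: AnalysisParams | None = None,
) -> RemapStats:
    """Remapping statistics between two environments.

    ``mean_activity_correlation`` averages per-cell map correlations over
    cells active in both environments; retention counts common place cells
    whose field moved by at most one bin. The Hodges-Ajne test asks whether
    field shifts are uniformly distributed around the track (global
    remapping).
    """
    params = params or AnalysisParams()
    if len(a.stats) != len(b.stats):
        raise InsufficientDataError("sessions do not share a registered cell index")
    both_active = a.active & b.active
    if not both_active.any():
        raise InsufficientDataError("no common active cells")
    corrs = [
        _map_correlation(a.maps[i], b.maps[i]) for i in np.nonzero(both_active)[0]
    ]
    common_place = a.place & b.place
    shifts = []
    circumference = a.circumference_cm
    la, lb = a.field_location_cm, b.field_location_cm
    for i in np.nonzero(common_place)[0]:
        if np.isfinite(la[i]) and np.isfinite(lb[i]):
            shifts.append(circular_shift_cm(la[i], lb[i], circumference))
    shifts = np.asarray(shifts)
    retained = (
        float(np.mean(np.abs(shifts) <= params.retention_cm))
        if shifts.size else np.nan
    )
    if shifts.size >= 4:
        m, p = hodges_ajne_test(shifts / circumference * 360.0)
    else:
        m, p = None, np.nan
    return RemapStats(
        n_common_active=int(both_active.sum()),
        n_common_place_cells=int(common_place.sum()),
        fraction_retaining_location=retained,
        mean_activity_correlation=float(np.nanmean(corrs)),
        shift_distribution_cm=shifts,
        hodges_ajne_m=m,
        hodges_ajne_p=p,
    )
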