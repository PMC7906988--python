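"""Place-cell classification: spatial information, shuffle null, field
detection, and the classification criteria.

A cell's spatial information (bits/event) follows the Skaggs estimator

    I = sum_i p_i (lambda_i / lbar) log2(lambda_i / lbar),
    lbar = sum_i p_i lambda_i,  p_i = occupancy_i / total occupancy,

computed from the raw (unsmoothed) occupancy-normalized rate map. Chance
level is the distribution of I after randomly reassigning the cell's
per-frame activity across moving frames (1,000 shuffles); a cell passes the
information criterion when its I exceeds 99% of the shuffled values.

Circular-track (1D) classification additionally requires events on at least
half of the laps and events in at least 5% of moving in-field frames;
open-field (2D) classification requires the information criterion plus
events in at least 2% of moving in-field frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label

from .behavior import AlignedSession, LapSegmentation
from .config import AnalysisParams
from .errors import NoFieldError, UndefinedInformationError
from .ratemap import (
    RateMap1D,
    RateMap2D,
    assign_linear_bins,
    linear_bin_edges,
    rate_map_1d,
    rate_map_2d,
    square_grid,
)

# ---------------------------------------------------------------------------
# Spatial information
# ---------------------------------------------------------------------------

def spatial_information(rate: np.ndarray, occupancy_s: np.ndarray) -> float:
    """Skaggs spatial information (bits/event) of a rate map.

    Bins with zero occupancy are ignored; bins with zero rate contribute 0
    (the x log x -> 0 limit). Raises when the occupancy-weighted mean rate
    is zero (information undefined).
    """
    rate = np.asarray(rate, dtype=float)
    occ = np.asarray(occupancy_s, dtype=float)
    use = (occ > 0) & np.isfinite(rate)
    if not np.any(use):
        raise UndefinedInformationError("no occupied bins")
    lam = rate[use]
    p = occ[use] / occ[use].sum()
    lbar = float(np.dot(p, lam))
    if lbar <= 0:
        raise UndefinedInformationError("mean rate is zero")
    ratio = lam / lbar
    nz = ratio > 0
    info = float(np.sum(p[nz] * ratio[nz] * np.log2(ratio[nz])))
    # information is non-negative (Jensen); clamp float round-off
    return max(info, 0.0)


def _skaggs_many(rates: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Row-wise Skaggs information for a shuffles x bins rate matrix."""
    lbar = rates @ p
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rates / lbar[:, None]
        terms = np.where(ratio > 0, ratio * np.log2(ratio), 0.0)
    return terms @ p


# ---------------------------------------------------------------------------
# Session binning (shared by information, shuffles and criteria)
# ---------------------------------------------------------------------------

@dataclass
class SessionBinning:
    """Bin assignment of each moving frame, shared across cells."""

    moving_idx: np.ndarray      # frame indices (into the session) used
    bins: np.ndarray            # bin index per moving frame (flattened for 2D)
    occupancy_s: np.ndarray     # per bin, over moving frames
    n_bins: int
    grid_shape: tuple | None = None   # (n, n) for 2D maps


def session_binning(
    session: AlignedSession, params: AnalysisParams | None = None
) -> SessionBinning:
    params = params or AnalysisParams()
    moving_idx = np.nonzero(session.moving)[0]
    dt = 1.0 / session.frame_rate
    if session.arena == "circular_track":
        edges = linear_bin_edges(session.circumference_cm, params.bin_size_cm)
        bins = assign_linear_bins(session.lin_pos_cm[moving_idx], edges)
        n_bins = len(edges) - 1
        occ = np.bincount(bins, minlength=n_bins) * dt
        return SessionBinning(moving_idx, bins, occ, n_bins)
    edges, _ = square_grid(params.arena_diameter_mm, params.bin_size_cm)
    n = len(edges) - 1
    ix = np.clip(np.searchsorted(edges, session.x[moving_idx] / 10.0, "right") - 1,
                 0, n - 1)
    iy = np.clip(np.searchsorted(edges, session.y[moving_idx] / 10.0, "right") - 1,
                 0, n - 1)
    bins = ix * n + iy
    occ = np.bincount(bins, minlength=n * n) * dt
    return SessionBinning(moving_idx, bins, occ, n * n, (n, n))


# ---------------------------------------------------------------------------
# Shuffle null
# ---------------------------------------------------------------------------

@dataclass
class ShuffleNull:
    true_info: float
    null: np.ndarray
    percentile: float           # 100 x fraction of null strictly below true I
    true_mean_rate: float = np.nan
    null_mean_rate: np.ndarray | None = None   # conserved by construction

    @property
    def passes(self) -> bool:
        return self.percentile >= 99.0


def shuffle_null(
    session: AlignedSession,
    cell: int,
    params: AnalysisParams | None = None,
    rng: np.random.Generator | int | None = None,
    binning: SessionBinning | None = None,
) -> ShuffleNull:
    """Shuffle distribution of spatial information for one cell.

    Each shuffle randomly permutes the cell's per-frame activity values
    across the moving frames (conserving event count and amplitudes exactly)
    and recomputes the Skaggs information. ``shuffle_mode = "rotate"``
    applies a random circular shift of the activity series instead.
    """
    params = params or AnalysisParams()
    rng = np.random.default_rng(rng)
    b = binning or session_binning(session, params)
    amps = session.activity[b.moving_idx, cell]
    nz = np.nonzero(amps > 0)[0]
    if nz.size == 0:
        raise UndefinedInformationError("cell has no events during moving frames")
    vals = amps[nz]
    occ = b.occupancy_s
    valid = occ > 0
    p = occ[valid] / occ[valid].sum()
    t_frames = b.bins.size

    true_rate = np.bincount(b.bins, weights=amps, minlength=b.n_bins)[valid] / occ[valid]
    true_info = float(_skaggs_many(true_rate[None, :], p)[0])

    null_rates = np.empty((params.n_shuffles, valid.sum()))
    for s in range(params.n_shuffles):
        if params.shuffle_mode == "rotate":
            shift = int(rng.integers(t_frames))
            frames = (nz + shift) % t_frames
        else:
            frames = rng.permutation(t_frames)[: nz.size]
        sums = np.bincount(b.bins[frames], weights=vals, minlength=b.n_bins)
        null_rates[s] = sums[valid] / occ[valid]
    null = _skaggs_many(null_rates, p)
    percentile = 100.0 * float(np.mean(null < true_info))
    return ShuffleNull(
        true_info, null, percentile,
        true_mean_rate=float(true_rate @ p),
        null_mean_rate=null_rates @ p,
    )


# ---------------------------------------------------------------------------
# Field detection
# ---------------------------------------------------------------------------

@dataclass
class PlaceField:
    """A detected place field.

    1D: ``location_bin``/``location_cm`` give the bin of maximum smoothed
    rate and its center; ``size`` is in cm. 2D: ``centroid_cm`` is the
    rate-weighted mean of member-bin centers and ``size`` is in cm^2.
    Member bins have (normalized) rate at/above the 0.5 threshold and are
    not required to be contiguous.
    """

    mode: str                   # "1d" | "2d"
    member_bins: np.ndarray
    size: float
    location_bin: int | None = None
    location_cm: float | None = None
    centroid_cm: tuple[float, float] | None = None
    degenerate: bool = False
    tie: bool = False
    multimodal: bool = False


def detect_field_1d(
    rm: RateMap1D, threshold: float = 0.5
) -> PlaceField:
    """Field = bins whose smoothed rate is at least ``threshold`` x maximum."""
    sm = rm.smoothed_rate
    finite = np.isfinite(sm)
    if not finite.any() or np.nanmax(sm) <= 0:
        raise NoFieldError("all-zero or empty map")
    peak = np.nanmax(sm)
    loc = int(np.nanargmax(sm))           # ties -> lowest bin index
    tie = int(np.sum(sm[finite] == peak)) > 1
    members = np.nonzero(finite & (sm >= threshold * peak))[0]
    widths = np.diff(rm.bin_edges)
    size = float(widths[members].sum())
    degenerate = members.size == int(finite.sum())
    return PlaceField(
        mode="1d",
        member_bins=members,
        size=size,
        location_bin=loc,
        location_cm=float(rm.bin_centers[loc]),
        degenerate=degenerate,
        tie=tie,
    )


def detect_field_2d(
    rm: RateMap2D, threshold: float = 0.5
) -> PlaceField:
    """Field = bins of the normalized map strictly above ``threshold``;
    location is their rate-weighted centroid."""
    nm = rm.normalized_rate
    finite = np.isfinite(nm)
    if not rm.has_activity or not finite.any():
        raise NoFieldError("all-zero or empty map")
    mask = finite & (nm > threshold)
    if not mask.any():
        raise NoFieldError("no bins above threshold")
    centers = rm.bin_centers
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    w = nm[mask]
    centroid = (float(np.sum(cx[mask] * w) / w.sum()),
                float(np.sum(cy[mask] * w) / w.sum()))
    bin_area = float(np.diff(rm.bin_edges)[0]) ** 2
    n_components = cc_label(mask)[1]
    uniform = np.allclose(nm[finite], nm[finite][0])
    return PlaceField(
        mode="2d",
        member_bins=np.column_stack(np.nonzero(mask)),
        size=float(mask.sum()) * bin_area,
        centroid_cm=centroid,
        degenerate=uniform,
        multimodal=n_components > 1,
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class PlaceCellStats:
    cell: int
    mode: str
    spatial_info: float = np.nan
    shuffle_percentile: float = np.nan
    lap_active_fraction: float = np.nan
    within_field_active_fraction: float = np.nan
    c1_laps: bool | None = None
    c2_field_occupancy: bool = False
    c3_information: bool = False
    is_place_cell: bool = False
    field: PlaceField | None = None
    n_events: int = 0
    reason: str = ""
    per_lap_argmax: np.ndarray | None = dc_field(default=None, repr=False)


def classify_place_cell(
    session: AlignedSession,
    cell: int,
    params: AnalysisParams | None = None,
    rng: np.random.Generator | int | None = None,
    laps: LapSegmentation | None = None,
    binning: SessionBinning | None = None,
) -> PlaceCellStats:
    """Apply the full classification criteria to one cell.

    1D (circular track): (1) events on at least half of the complete laps
    (within the detected field), (2) events in at least 5% of moving
    in-field frames, (3) spatial information above the 99th percentile of
    the shuffle null. 2D (open field): criteria (2) at 2% and (3).
    """
    params = params or AnalysisParams()
    mode = "1d" if session.arena == "circular_track" else "2d"
    stats = PlaceCellStats(cell=cell, mode=mode)
    b = binning or session_binning(session, params)
    amps = session.activity[b.moving_idx, cell]
    stats.n_events = int(np.sum(amps > 0))
    if stats.n_events == 0:
        stats.reason = "no_events"
        return stats

    if mode == "1d":
        rm = rate_map_1d(session, cell, params)
        try:
            fld = detect_field_1d(rm, params.field_threshold)
        except NoFieldError:
            stats.reason = "no_field"
            return stats
        stats.field = fld
        stats.spatial_info = spatial_information(rm.raw_rate, rm.occupancy_s)
        in_field = np.isin(b.bins, fld.member_bins)
        laps = laps or session.laps()
        lap_of_frame = laps.lap_index[b.moving_idx]
        complete_ids = [k for k, c in enumerate(laps.complete) if c]
        if complete_ids:
            event_frames = amps > 0
            scope = in_field if params.lap_event_scope == "field" else np.ones_like(in_field)
            active_laps = np.unique(lap_of_frame[event_frames & scope])
            n_active = np.isin(complete_ids, active_laps).sum()
            stats.lap_active_fraction = float(n_active / len(complete_ids))
            stats.c1_laps = stats.lap_active_fraction >= params.lap_fraction
            stats.per_lap_argmax = _per_lap_argmax(
                b, amps, lap_of_frame, complete_ids
            )
        else:
            stats.c1_laps = False
            stats.reason = "no_complete_laps"
        c2_threshold = params.infield_event_fraction_1d
    else:
        rm = rate_map_2d(session, cell, params)
        try:
            fld = detect_field_2d(rm, params.field_threshold)
        except NoFieldError:
            stats.reason = "no_field"
            return stats
        stats.field = fld
        stats.spatial_info = spatial_information(rm.raw_rate, rm.occupancy_s)
        n = rm.raw_rate.shape[0]
        flat_members = fld.member_bins[:, 0] * n + fld.member_bins[:, 1]
        in_field = np.isin(b.bins, flat_members)
        c2_threshold = params.infield_event_fraction_2d

    n_in_field = int(in_field.sum())
    if n_in_field > 0:
        stats.within_field_active_fraction = float(
            np.sum((amps > 0) & in_field) / n_in_field
        )
        stats.c2_field_occupancy = (
            stats.within_field_active_fraction >= c2_threshold
        )
    sh = shuffle_null(session, cell, params, rng, binning=b)
    stats.shuffle_percentile = sh.percentile
    stats.c3_information = sh.percentile >= params.shuffle_percentile
    if mode == "1d":
        stats.is_place_cell = bool(
            stats.c1_laps and stats.c2_field_occupancy and stats.c3_information
        )
    else:
        stats.is_place_cell = bool(stats.c2_field_occupancy and stats.c3_information)
    return stats


def _per_lap_argmax(
    b: SessionBinning,
    amps: np.ndarray,
    lap_of_frame: np.ndarray,
    complete_ids: list[int],
) -> np.ndarray:
    """Bin of maximum activity per complete lap (NaN for event-free laps).

    Exposes the lap-by-lap field trajectory (e.g. backward field shifts)
    without imposing a statistic on it.
    """
    out = np.full(len(complete_ids), np.nan)
    for i, k in enumerate(complete_ids):
        sel = lap_of_frame == k
        if np.any(amps[sel] > 0):
            sums = np.bincount(b.bins[sel], weights=amps[sel], minlength=b.n_bins)
            out[i] = float(np.argmax(sums))
    return out


def classify_population(
    session: AlignedSession,
    params: AnalysisParams | None = None,
    seed: int | np.random.Generator | None = 0,
    cells: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[PlaceCellStats]]:
    """Classify every cell of a session; returns a tidy table and full stats.

    Randomness (the shuffle null) flows from ``seed``; the same seed gives
    identical classifications.
    """
    params = params or AnalysisParams()
    rng = np.random.default_rng(seed)
    b = session_binning(session, params)
    laps = session.laps() if session.arena == "circular_track" else None
    cells = np.arange(session.n_cells) if cells is None else np.asarray(cells)
    all_stats = [
        classify_place_cell(session, int(c), params, rng, laps=laps, binning=b)
        for c in cells
    ]
    rows = []
    for st in all_stats:
        loc = np.nan
        size = np.nan
        if st.field is not None:
            size = st.field.size
            if st.mode == "1d":
                loc = st.field.location_cm
        rows.append({
            "cell": st.cell,
            "mode": st.mode,
            "n_events": st.n_events,
            "spatial_info_bits_per_event": st.spatial_info,
            "shuffle_percentile": st.shuffle_percentile,
            "lap_active_fraction": st.lap_active_fraction,
            "within_field_active_fraction": st.within_field_active_fraction,
            "c1_laps": st.c1_laps,
            "c2_field_occupancy": st.c2_field_occupancy,
            "c3_information": st.c3_information,
            "is_place_cell": st.is_place_cell,
            "field_location_cm": loc,
            "field_size": size,
            "reason": st.reason,
        })
    return pd.DataFrame(rows), all_stats
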