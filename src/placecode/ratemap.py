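"""Occupancy and activity-rate maps.

An activity-rate map accumulates the deconvolved dF/F amplitude emitted while
the animal occupies each spatial bin and divides by the time spent there
(units dF/F * s^-1); an event-rate map counts events instead (events/s).
1D maps use 2-cm bins along the track midline, smoothed with a circular
three-bin boxcar; 2D maps use 2 x 2 cm bins masked to the arena disc,
smoothed with a Gaussian kernel of sigma = 1.5 bins. Each smoothed map is
normalized by its maximum. Bins never visited are missing (NaN), not zero,
and stay missing through smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .behavior import AlignedSession, LapSegmentation
from .config import AnalysisParams
from .errors import EmptyMapError, InsufficientDataError, UnsupportedArenaError


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def linear_bin_edges(circumference_cm: float, bin_size_cm: float = 2.0) -> np.ndarray:
    """Edges of 1D bins over one circumference.

    The number of bins is round(C / bin_size); the first n-1 bins are exactly
    ``bin_size_cm`` wide and the last bin absorbs the rounding remainder.
    """
    n_bins = int(round(circumference_cm / bin_size_cm))
    if n_bins < 1:
        raise EmptyMapError("circumference shorter than one bin")
    edges = np.arange(n_bins + 1, dtype=float) * bin_size_cm
    edges[-1] = circumference_cm
    return edges


def assign_linear_bins(pos_cm: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """0-based bin index per sample; bins are half-open [left, right)."""
    idx = np.searchsorted(edges, pos_cm, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def square_grid(
    arena_diameter_mm: float, bin_size_cm: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """(edges_cm, in_arena mask) for the 2D grid covering the arena disc."""
    r = arena_diameter_mm / 10.0 / 2.0  # cm
    n = int(np.ceil(2 * r / bin_size_cm))
    edges = -r + np.arange(n + 1, dtype=float) * bin_size_cm
    centers = (edges[:-1] + edges[1:]) / 2.0
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    in_arena = np.hypot(cx, cy) <= r
    return edges, in_arena


# ---------------------------------------------------------------------------
# Smoothing (missing-aware, mass-preserving on fully valid maps)
# ---------------------------------------------------------------------------

def circular_boxcar(values: np.ndarray, width: int = 3) -> np.ndarray:
    """Circular boxcar average, NaN-aware and mass-preserving.

    Each bin's mass is redistributed with a kernel renormalized over its
    non-missing neighbours, so missing bins neither absorb nor leak rate
    mass and the total over valid bins is conserved exactly; bins missing
    on input stay missing.
    """
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    kernel = np.ones(width) / width
    den = _circular_convolve(ok.astype(float), kernel)
    w = np.where(ok & (den > 0), v / np.where(den > 0, den, 1.0), 0.0)
    out = _circular_convolve(w, kernel)
    out[~ok] = np.nan
    return out


def _circular_convolve(v: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    n = len(v)
    half = len(kernel) // 2
    padded = np.concatenate([v[-half:], v, v[:half]])
    return np.convolve(padded, kernel, mode="valid")[:n]


def masked_gaussian_smooth(
    values: np.ndarray, valid: np.ndarray, sigma_bins: float = 1.5
) -> np.ndarray:
    """2D Gaussian smoothing with kernel mass renormalized over valid bins.

    Each valid bin's rate mass is spread with a kernel renormalized to sum
    to one over the valid bins it can reach, so no mass attenuates into the
    wall or into unvisited bins and the total over valid bins is conserved
    exactly. Invalid bins remain NaN.
    """
    v = np.asarray(values, dtype=float)
    ok = valid & np.isfinite(v)
    den = gaussian_filter(ok.astype(float), sigma_bins, mode="constant")
    w = np.where(ok & (den > 0), v / np.where(den > 0, den, 1.0), 0.0)
    smoothed = gaussian_filter(w, sigma_bins, mode="constant")
    out = np.full_like(v, np.nan)
    out[ok] = smoothed[ok]
    return out


def _normalize(smoothed: np.ndarray) -> tuple[np.ndarray, bool]:
    """Map normalized by its smoothed maximum; flag degenerate all-zero maps."""
    finite = smoothed[np.isfinite(smoothed)]
    peak = finite.max() if finite.size else 0.0
    if peak <= 0:
        return np.where(np.isfinite(smoothed), 0.0, np.nan), False
    return smoothed / peak, True


# ---------------------------------------------------------------------------
# 1D rate maps
# ---------------------------------------------------------------------------

@dataclass
class RateMap1D:
    bin_edges: np.ndarray
    occupancy_s: np.ndarray
    raw_rate: np.ndarray        # dF/F * s^-1, NaN where unvisited
    event_rate: np.ndarray      # events/s
    smoothed_rate: np.ndarray
    normalized_rate: np.ndarray
    valid: np.ndarray           # occupancy > 0
    has_activity: bool

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def rate_map_1d(
    session: AlignedSession,
    cell: int,
    params: AnalysisParams | None = None,
    frame_mask: np.ndarray | None = None,
) -> RateMap1D:
    """Activity-rate map of one cell along the linearized track.

    Only moving frames contribute. ``frame_mask`` further restricts the frames
    used (e.g. to frames within complete laps).
    """
    params = params or AnalysisParams()
    if session.arena != "circular_track":
        raise UnsupportedArenaError("1D maps are defined on the circular track")
    use = session.moving if frame_mask is None else (session.moving & frame_mask)
    if not np.any(use):
        raise EmptyMapError("no moving frames")
    edges = linear_bin_edges(session.circumference_cm, params.bin_size_cm)
    n_bins = len(edges) - 1
    idx = assign_linear_bins(session.lin_pos_cm[use], edges)
    amps = session.activity[use, cell]
    dt = 1.0 / session.frame_rate
    occupancy = np.bincount(idx, minlength=n_bins) * dt
    amp_sum = np.bincount(idx, weights=amps, minlength=n_bins)
    ev_sum = np.bincount(idx, weights=(amps > 0).astype(float), minlength=n_bins)
    valid = occupancy > 0
    raw = np.full(n_bins, np.nan)
    evr = np.full(n_bins, np.nan)
    raw[valid] = amp_sum[valid] / occupancy[valid]
    evr[valid] = ev_sum[valid] / occupancy[valid]
    smoothed = circular_boxcar(raw, params.boxcar_bins)
    normalized, has_activity = _normalize(smoothed)
    return RateMap1D(edges, occupancy, raw, evr, smoothed, normalized, valid,
                     has_activity)


# ---------------------------------------------------------------------------
# 2D rate maps
# ---------------------------------------------------------------------------

@dataclass
class RateMap2D:
    bin_edges: np.ndarray       # shared by x and y
    in_arena: np.ndarray        # bins inside the disc
    occupancy_s: np.ndarray
    raw_rate: np.ndarray
    event_rate: np.ndarray
    smoothed_rate: np.ndarray
    normalized_rate: np.ndarray
    valid: np.ndarray           # in-arena and visited
    has_activity: bool

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def rate_map_2d(
    session: AlignedSession,
    cell: int,
    params: AnalysisParams | None = None,
) -> RateMap2D:
    """Activity-rate map of one cell on the 2 x 2 cm open-field grid."""
    params = params or AnalysisParams()
    if session.arena != "open_field":
        raise UnsupportedArenaError("2D maps are defined on the open field")
    use = session.moving
    if not np.any(use):
        raise EmptyMapError("no moving frames")
    edges, in_arena = square_grid(params.arena_diameter_mm, params.bin_size_cm)
    n = len(edges) - 1
    ix = np.clip(np.searchsorted(edges, session.x[use] / 10.0, "right") - 1, 0, n - 1)
    iy = np.clip(np.searchsorted(edges, session.y[use] / 10.0, "right") - 1, 0, n - 1)
    flat = ix * n + iy
    amps = session.activity[use, cell]
    dt = 1.0 / session.frame_rate
    occupancy = (np.bincount(flat, minlength=n * n) * dt).reshape(n, n)
    amp_sum = np.bincount(flat, weights=amps, minlength=n * n).reshape(n, n)
    ev_sum = np.bincount(
        flat, weights=(amps > 0).astype(float), minlength=n * n
    ).reshape(n, n)
    valid = (occupancy > 0) & in_arena
    raw = np.full((n, n), np.nan)
    evr = np.full((n, n), np.nan)
    raw[valid] = amp_sum[valid] / occupancy[valid]
    evr[valid] = ev_sum[valid] / occupancy[valid]
    smoothed = masked_gaussian_smooth(raw, valid, params.gaussian_sigma_bins)
    normalized, has_activity = _normalize(smoothed)
    return RateMap2D(edges, in_arena, occupancy, raw, evr, smoothed, normalized,
                     valid, has_activity)


# ---------------------------------------------------------------------------
# Per-lap maps
# ---------------------------------------------------------------------------

@dataclass
class LapRateMatrix:
    """laps x bins matrix of per-lap activity rate; unvisited bins are NaN."""

    rate: np.ndarray            # laps x bins, dF/F * s^-1
    event_rate: np.ndarray      # laps x bins, events/s
    occupancy_s: np.ndarray     # laps x bins
    bin_edges: np.ndarray
    lap_ids: np.ndarray         # indices into the session's LapSegmentation

    @property
    def n_laps(self) -> int:
        return self.rate.shape[0]


def per_lap_maps(
    session: AlignedSession,
    cell: int,
    laps: LapSegmentation | None = None,
    params: AnalysisParams | None = None,
    include_partial: bool = False,
) -> LapRateMatrix:
    """Per-lap, per-bin activity rates for one cell.

    Only moving frames contribute; bins not visited within a lap are missing
    (NaN), not zero. The occupancy-weighted mean across laps reconstructs the
    session map restricted to the same frames.
    """
    params = params or AnalysisParams()
    laps = laps or session.laps()
    lap_list = list(laps.laps) if include_partial else laps.complete_laps()
    lap_ids = [k for k, lap in enumerate(laps.laps)
               if include_partial or laps.complete[k]]
    if not lap_list:
        raise InsufficientDataError("no complete laps")
    edges = linear_bin_edges(session.circumference_cm, params.bin_size_cm)
    n_bins = len(edges) - 1
    dt = 1.0 / session.frame_rate
    moving = session.moving
    rate = np.full((len(lap_list), n_bins), np.nan)
    evr = np.full((len(lap_list), n_bins), np.nan)
    occ = np.zeros((len(lap_list), n_bins))
    for row, (s, e) in enumerate(lap_list):
        use = np.zeros(session.n_frames, dtype=bool)
        use[s:e] = True
        use &= moving
        if not np.any(use):
            continue
        idx = assign_linear_bins(session.lin_pos_cm[use], edges)
        amps = session.activity[use, cell]
        o = np.bincount(idx, minlength=n_bins) * dt
        a = np.bincount(idx, weights=amps, minlength=n_bins)
        ev = np.bincount(idx, weights=(amps > 0).astype(float), minlength=n_bins)
        visited = o > 0
        occ[row] = o
        rate[row, visited] = a[visited] / o[visited]
        evr[row, visited] = ev[visited] / o[visited]
    return LapRateMatrix(rate, evr, occ, edges, np.asarray(lap_ids))


def session_map_from_laps(lapmat: LapRateMatrix) -> np.ndarray:
    """Occupancy-weighted mean of per-lap rates (reconstructs the session map)."""
    occ = lapmat.occupancy_s
    num = np.nansum(np.where(occ > 0, lapmat.rate, 0.0) * occ, axis=0)
    den = occ.sum(axis=0)
    out = np.full(lapmat.rate.shape[1], np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out
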