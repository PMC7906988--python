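"""Behavioral preprocessing: tracking alignment, linearization, speed gating,
lap segmentation and coverage.

Tracking is sampled at ~100 Hz while imaging runs at ~30 Hz; every analysis
operates on behavior resampled onto the imaging frame clock. Position on the
circular track is expressed as an angle and linearized to distance along the
annulus midline using the known circumference. Only frames where the animal
moves faster than 20 mm/s enter any spatial map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .config import AnalysisParams, OUTER_DIAMETER_MM
from .errors import AlignmentError, UnsupportedArenaError

ARENAS = ("circular_track", "open_field")


# ---------------------------------------------------------------------------
# Trajectory (tracking-rate behavior)
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Position tracking time series (tracking rate, ~100 Hz).

    Coordinates are in mm, centered on the arena center. ``theta`` (degrees,
    [0, 360), counter-clockwise) and ``radius`` are derived from x, y.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena: str = "circular_track"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.arena not in ARENAS:
            raise UnsupportedArenaError(f"unknown arena {self.arena!r}")
        if self.t.size < 2:
            raise AlignmentError("trajectory needs at least two samples")
        if not np.all(np.diff(self.t) > 0):
            raise AlignmentError("timestamps must be strictly increasing")

    @property
    def theta(self) -> np.ndarray:
        """Angular position in degrees, [0, 360)."""
        return np.mod(np.degrees(np.arctan2(self.y, self.x)), 360.0)

    @property
    def radius(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    @property
    def speed(self) -> np.ndarray:
        """Instantaneous speed (mm/s) from central differences."""
        return _central_diff_speed(self.t, self.x, self.y)


def _central_diff_speed(t: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = np.gradient(x, t)
    dy = np.gradient(y, t)
    return np.hypot(dx, dy)


# ---------------------------------------------------------------------------
# Alignment to imaging frames
# ---------------------------------------------------------------------------

def align_tracking(
    traj: Trajectory,
    frame_times: np.ndarray,
    max_gap_s: float = 0.5,
    speed_median_frames: int = 5,
) -> dict:
    """Resample tracking onto imaging frame times.

    Positions are linearly interpolated; speed is recomputed from the
    interpolated positions (central differences) and median-filtered over
    ``speed_median_frames`` frames. Frames outside the tracking span, or
    spanned by a tracking gap longer than ``max_gap_s``, are flagged invalid.

    Returns a dict with keys x, y, speed (arrays per frame) and valid (bool).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size < 2:
        raise AlignmentError("need at least two imaging frames")
    if frame_times[0] > traj.t[-1] or frame_times[-1] < traj.t[0]:
        raise AlignmentError("no temporal overlap between tracking and imaging")

    x = np.interp(frame_times, traj.t, traj.x)
    y = np.interp(frame_times, traj.t, traj.y)
    valid = (frame_times >= traj.t[0]) & (frame_times <= traj.t[-1])

    # frames spanned by a tracking dropout are unreliable interpolations
    gaps = np.diff(traj.t)
    for i in np.nonzero(gaps > max_gap_s)[0]:
        valid &= ~((frame_times > traj.t[i]) & (frame_times < traj.t[i + 1]))

    speed = _central_diff_speed(frame_times, x, y)
    if speed_median_frames > 1:
        speed = median_filter(speed, size=speed_median_frames, mode="nearest")
    return {"x": x, "y": y, "speed": speed, "valid": valid}


# ---------------------------------------------------------------------------
# Linearization and laps
# ---------------------------------------------------------------------------

def linearize_position(
    theta_deg: np.ndarray, circumference_cm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Convert angular position to distance along the track midline.

    Returns ``(within_lap_cm, cumulative_cm)``: the within-lap position
    (theta/360 * C, in [0, C)) and the unwrapped cumulative distance, which
    is monotone while the animal runs forward and handles 350->10 degree
    wrap-around crossings.
    """
    if circumference_cm <= 0:
        raise ValueError("circumference must be positive")
    theta = np.mod(np.asarray(theta_deg, dtype=float), 360.0)
    within = theta / 360.0 * circumference_cm
    unwrapped = np.unwrap(np.radians(theta))
    cumulative = (unwrapped - unwrapped[0]) / (2 * np.pi) * circumference_cm
    return within, cumulative


def moving_mask(speed_mm_s: np.ndarray, threshold_mm_s: float = 20.0) -> np.ndarray:
    """Boolean mask of frames with speed strictly above threshold."""
    return np.asarray(speed_mm_s) > threshold_mm_s


def running_fraction(speed_mm_s: np.ndarray, threshold_mm_s: float = 20.0) -> float:
    m = moving_mask(speed_mm_s, threshold_mm_s)
    return float(np.mean(m)) if m.size else 0.0


@dataclass
class LapSegmentation:
    """Lap boundaries on a circular-track session.

    ``laps`` holds (start_frame, end_frame) half-open intervals; laps are
    non-overlapping and ordered. ``complete`` flags laps spanning one full
    circumference of cumulative distance; at most the final lap is partial.
    ``lap_index`` maps each frame to its lap (or -1 before the first start).
    """

    laps: list[tuple[int, int]]
    complete: np.ndarray
    lap_index: np.ndarray

    @property
    def n_complete(self) -> int:
        return int(np.sum(self.complete))

    def complete_laps(self) -> list[tuple[int, int]]:
        return [lap for lap, c in zip(self.laps, self.complete) if c]


def segment_laps(cumulative_cm: np.ndarray, circumference_cm: float) -> LapSegmentation:
    """Segment a cumulative-distance series into laps.

    A new lap boundary is placed each time cumulative distance advances one
    full circumference past the previous boundary; net backward excursions
    therefore never accrue laps. The trailing partial lap is retained and
    flagged incomplete.
    """
    cum = np.asarray(cumulative_cm, dtype=float)
    n = cum.size
    starts = [0]
    boundary = cum[0] + circumference_cm
    for i in range(1, n):
        if cum[i] >= boundary:
            starts.append(i)
            boundary = boundary + circumference_cm
    laps: list[tuple[int, int]] = []
    complete = []
    for k, s in enumerate(starts):
        e = starts[k + 1] if k + 1 < len(starts) else n
        laps.append((s, e))
        complete.append(k + 1 < len(starts))
    lap_index = np.full(n, -1, dtype=int)
    for k, (s, e) in enumerate(laps):
        lap_index[s:e] = k
    return LapSegmentation(laps, np.asarray(complete, bool), lap_index)


def coverage_fraction(
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    arena_diameter_mm: float = OUTER_DIAMETER_MM,
    bin_size_cm: float = 2.0,
) -> float:
    """Fraction of in-arena square bins visited at least once (open field)."""
    bs = bin_size_cm * 10.0  # mm
    r = arena_diameter_mm / 2.0
    edges = np.arange(-r, r + bs, bs)
    centers = (edges[:-1] + edges[1:]) / 2.0
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    in_arena = np.hypot(cx, cy) <= r
    ix = np.clip(np.digitize(x_mm, edges) - 1, 0, centers.size - 1)
    iy = np.clip(np.digitize(y_mm, edges) - 1, 0, centers.size - 1)
    visited = np.zeros_like(in_arena, dtype=bool)
    visited[ix, iy] = True
    return float(np.sum(visited & in_arena) / np.sum(in_arena))


# ---------------------------------------------------------------------------
# AlignedSession (the join of behavior and neural data)
# ---------------------------------------------------------------------------

@dataclass
class AlignedSession:
    """Behavior resampled to imaging frames, joined with population activity.

    ``activity`` is the frames x cells matrix of non-negative deconvolved
    calcium-transient amplitudes (dimensionless dF/F units). ``moving``
    marks frames with speed strictly above the gating threshold AND valid
    tracking; all spatial maps are built from these frames only.
    """

    frame_times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray
    activity: np.ndarray
    frame_rate: float
    arena: str
    circumference_cm: float | None = None
    environment: str = "A"
    day: int = 0
    valid: np.ndarray | None = None
    speed_threshold_mm_s: float = 20.0
    lin_pos_cm: np.ndarray | None = field(default=None, repr=False)
    cum_dist_cm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        n = len(self.frame_times)
        if self.activity.shape[0] != n:
            raise AlignmentError(
                f"activity has {self.activity.shape[0]} frames, behavior has {n}"
            )
        if np.any(self.activity < 0):
            raise ValueError("event amplitudes must be non-negative")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        if self.arena == "circular_track" and self.lin_pos_cm is None:
            if self.circumference_cm is None:
                self.circumference_cm = AnalysisParams().circumference_cm
            theta = np.mod(np.degrees(np.arctan2(self.y, self.x)), 360.0)
            self.lin_pos_cm, self.cum_dist_cm = linearize_position(
                theta, self.circumference_cm
            )

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def n_cells(self) -> int:
        return self.activity.shape[1]

    @property
    def theta(self) -> np.ndarray:
        return np.mod(np.degrees(np.arctan2(self.y, self.x)), 360.0)

    @property
    def moving(self) -> np.ndarray:
        return moving_mask(self.speed, self.speed_threshold_mm_s) & self.valid

    @property
    def running_fraction(self) -> float:
        return float(np.mean(moving_mask(self.speed, self.speed_threshold_mm_s)))

    def laps(self) -> LapSegmentation:
        if self.arena != "circular_track":
            raise UnsupportedArenaError("laps are defined on the circular track only")
        return segment_laps(self.cum_dist_cm, self.circumference_cm)


def session_from_trajectory(
    traj: Trajectory,
    activity: np.ndarray,
    frame_rate: float,
    params: AnalysisParams | None = None,
    environment: str = "A",
    day: int = 0,
) -> AlignedSession:
    """Align a tracking trajectory with an activity matrix into a session."""
    params = params or AnalysisParams()
    n_frames = np.asarray(activity).shape[0]
    frame_times = traj.t[0] + np.arange(n_frames) / frame_rate
    frame_times = frame_times[frame_times <= traj.t[-1] + 1.0 / frame_rate]
    aligned = align_tracking(
        traj, frame_times, params.max_gap_s, params.speed_median_frames
    )
    return AlignedSession(
        frame_times=frame_times,
        x=aligned["x"][: len(frame_times)],
        y=aligned["y"][: len(frame_times)],
        speed=aligned["speed"][: len(frame_times)],
        activity=np.asarray(activity)[: len(frame_times)],
        frame_rate=frame_rate,
        arena=traj.arena,
        circumference_cm=params.circumference_cm,
        environment=environment,
        day=day,
        valid=aligned["valid"][: len(frame_times)],
        speed_threshold_mm_s=params.speed_threshold_mm_s,
    )
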