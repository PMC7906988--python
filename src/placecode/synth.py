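"""Synthetic floating-track sessions: trajectories, tuned cell populations,
and multi-session studies.

The generator emulates the behavioral and neural statistics the analysis
assumes: a head-fixed mouse propelling a circular track (outer diameter
325 mm, width 50 mm) in smooth angular laps with occasional pauses, or
meandering across a 325-mm circular open field with >90% coverage in 45 min;
cells emitting amplitude-marked deconvolved calcium events at the imaging
rate, either spatially tuned (unimodal 1D circular or 2D Gaussian fields,
expressed only on a fraction of laps), untuned (homogeneous), or
homogeneous-Poisson controls. Multi-session studies support global
remapping between environments, day-to-day field drift, and probabilistic
cell recurrence. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .behavior import AlignedSession, Trajectory, session_from_trajectory
from .config import AnalysisParams
from .errors import InvalidConfigError

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a trained mouse in a 30-minute circular-track session:
    running at 120 +/- 30 mm/s with brief pauses, 100 place cells with
    60-degree-wide fields expressed on 72% of laps, peak in-field event rate
    4 events/s over a 0.05 events/s background, untuned cells at the
    0.46 events/s typical of non-place-sensitive cells, and log-normal event
    amplitudes. Rates are events/s; amplitudes are dimensionless dF/F.
    """

    arena: str = "circular_track"
    outer_diameter_mm: float = 325.0
    track_width_mm: float = 50.0
    duration_s: float = 1800.0
    frame_rate_hz: float = 30.0
    tracking_rate_hz: float = 100.0
    # speed profile
    speed_mean_mm_s: float = 120.0
    speed_sd_mm_s: float = 30.0
    speed_tau_s: float = 1.0
    pause_prob_per_s: float = 0.02
    pause_duration_s: float = 2.0
    # population composition
    n_place_cells: int = 100
    n_untuned_cells: int = 100
    n_poisson_cells: int = 0
    # tuning
    field_width_deg: float = 60.0       # 1D full width at half maximum
    field_width_mm: float = 80.0        # 2D full width at half maximum
    peak_event_rate: float = 4.0
    background_event_rate: float = 0.05
    untuned_event_rate: float = 0.46
    poisson_event_rate: float = 1.0
    lap_reliability: float = 0.72
    # amplitudes: log-normal(mu, sigma) of dF/F, or a fixed value
    amplitude_mu: float = -0.5
    amplitude_sigma: float = 0.6
    amplitude_fixed: float | None = None
    # multi-session structure
    remap: bool = True                  # independent fields across environments
    recurrence_prob: float = 0.9
    drift_deg_sd_per_day: float = 0.0
    # open-field walk
    heading_tau_s: float = 2.0
    wall_margin_mm: float = 12.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.arena not in ("circular_track", "open_field"):
            raise InvalidConfigError(f"unknown arena {self.arena!r}")
        if self.duration_s <= 0:
            raise InvalidConfigError("duration must be positive")
        for name in ("frame_rate_hz", "tracking_rate_hz"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        for name in (
            "speed_mean_mm_s", "speed_sd_mm_s", "peak_event_rate",
            "background_event_rate", "untuned_event_rate",
            "poisson_event_rate", "pause_prob_per_s", "pause_duration_s",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        for name in ("lap_reliability", "recurrence_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        for name in ("n_place_cells", "n_untuned_cells", "n_poisson_cells"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")

    @property
    def midline_radius_mm(self) -> float:
        return (self.outer_diameter_mm - self.track_width_mm) / 2.0

    @property
    def n_cells(self) -> int:
        return self.n_place_cells + self.n_untuned_cells + self.n_poisson_cells


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _ar1(n: int, tau_s: float, sd: float, dt: float,
         rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean AR(1) (discretized Ornstein-Uhlenbeck)."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-dt / tau_s)
    eps = rng.standard_normal(n) * sd * np.sqrt(1.0 - phi ** 2)
    eps[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -phi], eps)


def _pause_mask(n: int, dt: float, prob_per_s: float, duration_s: float,
                rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    if prob_per_s <= 0 or duration_s <= 0:
        return mask
    starts = np.nonzero(rng.random(n) < prob_per_s * dt)[0]
    for s in starts:
        dur = max(1, int(round(rng.exponential(duration_s) / dt)))
        mask[s:s + dur] = True
    return mask


def simulate_trajectory(
    config: SimConfig, rng: np.random.Generator | None = None
) -> Trajectory:
    """Simulate a tracking-rate trajectory for the configured arena.

    Circular track: angular motion on the annulus midline with an
    Ornstein-Uhlenbeck speed profile (clipped at zero) and pause episodes.
    Open field: an Ornstein-Uhlenbeck velocity walk reflected at the wall,
    which mixes wall-following stretches with arena crossings.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    dt = 1.0 / config.tracking_rate_hz
    n = int(round(config.duration_s * config.tracking_rate_hz)) + 1
    t = np.arange(n) * dt
    pause = _pause_mask(n, dt, config.pause_prob_per_s,
                        config.pause_duration_s, rng)

    if config.arena == "circular_track":
        v = config.speed_mean_mm_s + _ar1(
            n, config.speed_tau_s, config.speed_sd_mm_s, dt, rng
        )
        v = np.clip(v, 0.0, None)
        v[pause] = 0.0
        r = config.midline_radius_mm
        theta = np.concatenate([[0.0], np.cumsum(v[:-1] * dt) / r])
        return Trajectory(t=t, x=r * np.cos(theta), y=r * np.sin(theta),
                          arena="circular_track")

    # open field: OU velocity, reflecting wall
    r_max = config.outer_diameter_mm / 2.0 - config.wall_margin_mm
    sigma_v = config.speed_mean_mm_s / np.sqrt(np.pi / 2.0)
    vx = _ar1(n, config.heading_tau_s, sigma_v, dt, rng)
    vy = _ar1(n, config.heading_tau_s, sigma_v, dt, rng)
    vx[pause] = 0.0
    vy[pause] = 0.0
    x = np.empty(n)
    y = np.empty(n)
    px = py = 0.0
    for i in range(n):
        x[i], y[i] = px, py
        nx, ny = px + vx[i] * dt, py + vy[i] * dt
        rr = np.hypot(nx, ny)
        if rr > r_max:
            # reflect the velocity about the wall normal for the rest of
            # the correlated stretch, then clamp the position to the wall
            ux, uy = nx / rr, ny / rr
            vn = vx[i] * ux + vy[i] * uy
            vx[i:] -= 2 * vn * ux * np.exp(-(t[i:] - t[i]) / config.heading_tau_s)
            vy[i:] -= 2 * vn * uy * np.exp(-(t[i:] - t[i]) / config.heading_tau_s)
            nx, ny = ux * r_max, uy * r_max
        px, py = nx, ny
    return Trajectory(t=t, x=x, y=y, arena="open_field")


# ---------------------------------------------------------------------------
# Ground truth and tuning curves
# ---------------------------------------------------------------------------

CELL_KINDS = ("place", "untuned", "poisson")


def draw_ground_truth(
    config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-cell ground truth: kind, field center, width, peak rate.

    Field centers are uniform on the track circle (1D) or uniform over the
    arena disc away from the wall (2D); untuned and Poisson cells have no
    center (NaN).
    """
    kinds = (["place"] * config.n_place_cells
             + ["untuned"] * config.n_untuned_cells
             + ["poisson"] * config.n_poisson_cells)
    n = len(kinds)
    gt = pd.DataFrame({
        "cell": np.arange(n),
        "kind": kinds,
        "center_deg": np.nan,
        "center_x_mm": np.nan,
        "center_y_mm": np.nan,
        "field_width": np.nan,
        "peak_rate": np.nan,
    })
    place = gt["kind"] == "place"
    n_place = int(place.sum())
    if n_place:
        if config.arena == "circular_track":
            gt.loc[place, "center_deg"] = rng.uniform(0, 360, n_place)
            gt.loc[place, "field_width"] = config.field_width_deg
        else:
            r_field = config.outer_diameter_mm / 2.0 - 20.0
            rad = r_field * np.sqrt(rng.uniform(0, 1, n_place))
            ang = rng.uniform(0, 2 * np.pi, n_place)
            gt.loc[place, "center_x_mm"] = rad * np.cos(ang)
            gt.loc[place, "center_y_mm"] = rad * np.sin(ang)
            gt.loc[place, "field_width"] = config.field_width_mm
        gt.loc[place, "peak_rate"] = config.peak_event_rate
    gt.loc[gt["kind"] == "untuned", "peak_rate"] = config.untuned_event_rate
    gt.loc[gt["kind"] == "poisson", "peak_rate"] = config.poisson_event_rate
    gt["participates"] = True
    return gt


def tuning_rate_1d(
    theta_deg: np.ndarray, center_deg: float, fwhm_deg: float,
    peak: float, background: float = 0.0,
) -> np.ndarray:
    """Circular (von Mises-shaped) tuning curve, parameterized by FWHM."""
    delta = np.radians(theta_deg - center_deg)
    kappa = np.log(2.0) / (1.0 - np.cos(np.radians(fwhm_deg) / 2.0))
    return background + peak * np.exp(kappa * (np.cos(delta) - 1.0))


def tuning_rate_2d(
    x_mm: np.ndarray, y_mm: np.ndarray, cx: float, cy: float,
    fwhm_mm: float, peak: float, background: float = 0.0,
) -> np.ndarray:
    """Isotropic Gaussian tuning curve, parameterized by FWHM."""
    sigma = fwhm_mm / 2.3548200450309493
    d2 = (x_mm - cx) ** 2 + (y_mm - cy) ** 2
    return background + peak * np.exp(-d2 / (2.0 * sigma ** 2))


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------

def simulate_cells(
    config: SimConfig,
    traj: Trajectory,
    rng: np.random.Generator | None = None,
    ground_truth: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate the frames x cells activity matrix for a trajectory.

    Each cell emits events from a per-frame Bernoulli process with
    p = rate * dt (rates are well below the frame rate). Tuned rates follow
    the cell's tuning curve at the animal's position and, on the track, are
    gated per lap by ``lap_reliability``; untuned and Poisson cells are
    position-independent. Event amplitudes are log-normal (or fixed);
    non-participating cells stay silent.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if traj.t.size < 2:
        raise InvalidConfigError("empty trajectory")
    gt = draw_ground_truth(config, rng) if ground_truth is None else ground_truth
    dt = 1.0 / config.frame_rate_hz
    frame_times = np.arange(0.0, config.duration_s, dt) + traj.t[0]
    frame_times = frame_times[frame_times <= traj.t[-1]]
    n_frames = frame_times.size
    x = np.interp(frame_times, traj.t, traj.x)
    y = np.interp(frame_times, traj.t, traj.y)
    theta = np.mod(np.degrees(np.arctan2(y, x)), 360.0)

    lap_of_frame = None
    if config.arena == "circular_track":
        unwrapped = np.unwrap(np.radians(theta))
        lap_of_frame = np.floor((unwrapped - unwrapped[0]) / (2 * np.pi)).astype(int)
        lap_of_frame -= lap_of_frame.min()
        n_laps = lap_of_frame.max() + 1

    rates = np.empty((n_frames, len(gt)))
    for i, row in gt.iterrows():
        if not row["participates"]:
            rates[:, i] = 0.0
            continue
        if row["kind"] == "place":
            if config.arena == "circular_track":
                tuned = tuning_rate_1d(
                    theta, row["center_deg"], row["field_width"],
                    row["peak_rate"],
                )
                if config.lap_reliability < 1.0:
                    expressed = (
                        rng.random(n_laps) < config.lap_reliability
                    )[lap_of_frame]
                    tuned = tuned * expressed
            else:
                tuned = tuning_rate_2d(
                    x, y, row["center_x_mm"], row["center_y_mm"],
                    row["field_width"], row["peak_rate"],
                )
            rates[:, i] = tuned + config.background_event_rate
        else:
            rates[:, i] = row["peak_rate"]

    p = np.clip(rates * dt, 0.0, 1.0)
    events = rng.random(p.shape) < p
    if config.amplitude_fixed is not None:
        amps = np.full(p.shape, float(config.amplitude_fixed))
    else:
        amps = rng.lognormal(config.amplitude_mu, config.amplitude_sigma, p.shape)
    return np.where(events, amps, 0.0), gt


def simulate_session(
    config: SimConfig,
    environment: str = "A",
    day: int = 0,
    rng: np.random.Generator | None = None,
    ground_truth: pd.DataFrame | None = None,
    params: AnalysisParams | None = None,
) -> tuple[AlignedSession, pd.DataFrame]:
    """Simulate one aligned session (trajectory + activity, frame-aligned)."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    traj = simulate_trajectory(config, rng)
    activity, gt = simulate_cells(config, traj, rng, ground_truth)
    params = params or AnalysisParams(
        circumference_cm=np.pi * config.midline_radius_mm / 5.0,
        arena_diameter_mm=config.outer_diameter_mm,
    )
    session = session_from_trajectory(
        traj, activity, config.frame_rate_hz, params,
        environment=environment, day=day,
    )
    return session, gt


# ---------------------------------------------------------------------------
# Multi-session studies
# ---------------------------------------------------------------------------

def simulate_study(
    config: SimConfig,
    n_sessions: int,
    environments: list[str] | None = None,
    days: list[int] | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[AlignedSession, pd.DataFrame]]:
    """Simulate a study of ``n_sessions`` registered sessions.

    The same environment re-uses field centers (plus configured per-day
    circular drift); with ``remap=True`` each new environment draws centers
    independently and uniformly. From the second session on, each cell
    participates with probability ``recurrence_prob``; non-participating
    cells are silent that day.
    """
    if n_sessions < 1:
        raise InvalidConfigError("need at least one session")
    environments = environments or ["A"] * n_sessions
    if len(environments) != n_sessions:
        raise InvalidConfigError("need one environment label per session")
    for env in environments:
        if not isinstance(env, str) or not env:
            raise InvalidConfigError(f"unknown environment label {env!r}")
    days = days if days is not None else list(range(n_sessions))
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng

    base: dict[str, pd.DataFrame] = {}
    out = []
    last_day: dict[str, int] = {}
    for k in range(n_sessions):
        env, day = environments[k], days[k]
        if env not in base:
            if base and not config.remap:
                gt = next(iter(base.values())).copy()
            else:
                gt = draw_ground_truth(config, rng)
            base[env] = gt
        gt = base[env].copy()
        if config.drift_deg_sd_per_day > 0 and env in last_day:
            gap = max(day - last_day[env], 0)
            place = gt["kind"] == "place"
            drift = rng.normal(
                0.0, config.drift_deg_sd_per_day * np.sqrt(max(gap, 1)),
                int(place.sum()),
            )
            gt.loc[place, "center_deg"] = np.mod(
                gt.loc[place, "center_deg"] + drift, 360.0
            )
            base[env] = gt.copy()
        last_day[env] = day
        if k > 0:
            gt["participates"] = rng.random(len(gt)) < config.recurrence_prob
        session, gt = simulate_session(
            config, environment=env, day=day, rng=rng, ground_truth=gt
        )
        out.append((session, gt))
    return out


# ---------------------------------------------------------------------------
# Deterministic populations for manifold analyses
# ---------------------------------------------------------------------------

def noiseless_ring_population(
    theta_deg: np.ndarray, n_cells: int = 64, field_width_deg: float = 90.0
) -> np.ndarray:
    """Noiseless rates of cells whose fields evenly tile the ring.

    Returns cells x frames; each row is a circular tuning curve evaluated at
    the trajectory angle. Useful as a ground-truth population for manifold
    and decoding checks.
    """
    centers = np.arange(n_cells) / n_cells * 360.0
    return np.vstack([
        tuning_rate_1d(np.asarray(theta_deg), c, field_width_deg, 1.0)
        for c in centers
    ])


def noiseless_planar_population(
    x_mm: np.ndarray, y_mm: np.ndarray, n_cells: int = 64,
    arena_diameter_mm: float = 325.0, field_width_mm: float = 80.0,
) -> np.ndarray:
    """Noiseless rates of cells whose Gaussian fields tile the arena disc."""
    r = arena_diameter_mm / 2.0
    side = int(np.ceil(np.sqrt(n_cells / (np.pi / 4.0))))
    grid = np.linspace(-r, r, side)
    cx, cy = np.meshgrid(grid, grid, indexing="ij")
    inside = np.hypot(cx, cy) <= r
    centers = np.column_stack([cx[inside], cy[inside]])[:n_cells]
    return np.vstack([
        tuning_rate_2d(np.asarray(x_mm), np.asarray(y_mm), c[0], c[1],
                       field_width_mm, 1.0)
        for c in centers
    ])
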