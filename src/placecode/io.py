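"""Readers and writers for the pipeline's file formats.

Tracking is a CSV with columns t_s, x_mm, y_mm (header required; optional
theta_deg). Activity is an HDF5 file with a frames x cells dataset
"activity" and attributes frame_rate and arena (a CSV fallback with the
same layout is supported). Ground truth and results are plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import AlignedSession, Trajectory, session_from_trajectory
from .config import AnalysisParams
from .errors import ParseError

# ---------------------------------------------------------------------------
# Tracking CSV
# ---------------------------------------------------------------------------

def write_tracking_csv(path: str | Path, traj: Trajectory) -> None:
    pd.DataFrame({
        "t_s": traj.t, "x_mm": traj.x, "y_mm": traj.y,
        "theta_deg": traj.theta,
    }).to_csv(path, index=False)


def read_tracking_csv(path: str | Path, arena: str = "circular_track") -> Trajectory:
    df = pd.read_csv(path)
    missing = {"t_s", "x_mm", "y_mm"} - set(df.columns)
    if missing:
        raise ParseError(f"tracking file missing columns {sorted(missing)}")
    t = df["t_s"].to_numpy(float)
    if not np.all(np.diff(t) > 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 1
        raise ParseError(f"non-monotone timestamps at row {bad}")
    return Trajectory(t=t, x=df["x_mm"].to_numpy(float),
                      y=df["y_mm"].to_numpy(float), arena=arena)


# ---------------------------------------------------------------------------
# Activity HDF5 (CSV fallback)
# ---------------------------------------------------------------------------

def write_activity_h5(
    path: str | Path, activity: np.ndarray, frame_rate: float, arena: str
) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("activity", data=np.asarray(activity, float))
        ds.attrs["frame_rate"] = frame_rate
        ds.attrs["arena"] = arena


def read_activity_h5(path: str | Path) -> tuple[np.ndarray, float, str]:
    with h5py.File(path, "r") as fh:
        if "activity" not in fh:
            raise ParseError("activity file lacks an 'activity' dataset")
        ds = fh["activity"]
        activity = ds[()]
        frame_rate = float(ds.attrs.get("frame_rate", np.nan))
        arena = str(ds.attrs.get("arena", "circular_track"))
    _validate_activity(activity)
    return activity, frame_rate, arena


def write_activity_csv(path: str | Path, activity: np.ndarray) -> None:
    pd.DataFrame(np.asarray(activity, float)).to_csv(path, index=False)


def read_activity_csv(path: str | Path) -> np.ndarray:
    activity = pd.read_csv(path).to_numpy(float)
    _validate_activity(activity)
    return activity


def _validate_activity(activity: np.ndarray) -> None:
    if activity.ndim != 2:
        raise ParseError("activity must be a frames x cells matrix")
    neg = np.argwhere(activity < 0)
    if neg.size:
        frame, cell = neg[0]
        raise ParseError(
            f"negative amplitude at frame {frame}, cell {cell}"
        )


# ---------------------------------------------------------------------------
# Session bundles
# ---------------------------------------------------------------------------

@dataclass
class SessionBundle:
    """Pointers to one session's files plus metadata."""

    tracking_path: str | Path
    activity_path: str | Path
    arena: str = "circular_track"
    environment: str = "A"
    day: int = 0
    frame_rate: float | None = None   # overrides the file attribute


def load_session(
    bundle: SessionBundle, params: AnalysisParams | None = None
) -> AlignedSession:
    """Load, validate and align one session from its files."""
    params = params or AnalysisParams()
    traj = read_tracking_csv(bundle.tracking_path, bundle.arena)
    path = Path(bundle.activity_path)
    if path.suffix in (".h5", ".hdf5"):
        activity, frame_rate, _ = read_activity_h5(path)
    else:
        activity = read_activity_csv(path)
        frame_rate = np.nan
    if bundle.frame_rate is not None:
        frame_rate = bundle.frame_rate
    if not np.isfinite(frame_rate):
        raise ParseError("frame rate not recorded in file nor bundle")
    return session_from_trajectory(
        traj, activity, frame_rate, params,
        environment=bundle.environment, day=bundle.day,
    )


def write_embedding_h5(path: str | Path, emb, theta_deg=None) -> None:
    """Write a manifold embedding: eigenvalues, components, frame labels."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("eigenvalues", data=emb.eigenvalues)
        fh.create_dataset("components", data=emb.components)
        fh.create_dataset("variance_explained", data=emb.variance_explained)
        if emb.kept_frames is not None:
            fh.create_dataset("kept_frames", data=emb.kept_frames)
        if theta_deg is not None:
            fh.create_dataset("theta_deg", data=np.asarray(theta_deg))
        fh.attrs["method"] = emb.method


def write_maps_h5(path: str | Path, maps: dict[int, object]) -> None:
    """Write rate maps as one HDF5 group per cell (1D or 2D maps)."""
    with h5py.File(path, "w") as fh:
        for cell, rm in maps.items():
            grp = fh.create_group(f"cell_{cell}")
            grp.create_dataset("occupancy_s", data=rm.occupancy_s)
            grp.create_dataset("raw_rate", data=rm.raw_rate)
            grp.create_dataset("smoothed_rate", data=rm.smoothed_rate)
            grp.create_dataset("normalized_rate", data=rm.normalized_rate)
            grp.create_dataset("bin_edges", data=rm.bin_edges)


def write_session(
    directory: str | Path,
    traj: Trajectory,
    activity: np.ndarray,
    frame_rate: float,
    ground_truth: pd.DataFrame | None = None,
    prefix: str = "session",
) -> SessionBundle:
    """Write a (typically simulated) session in the pipeline's own formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tracking = directory / f"{prefix}_tracking.csv"
    act = directory / f"{prefix}_activity.h5"
    write_tracking_csv(tracking, traj)
    write_activity_h5(act, activity, frame_rate, traj.arena)
    if ground_truth is not None:
        ground_truth.to_csv(directory / f"{prefix}_ground_truth.csv", index=False)
    return SessionBundle(tracking, act, arena=traj.arena, frame_rate=frame_rate)
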