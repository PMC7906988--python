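"""Analysis parameters.

Every threshold used by the pipeline lives here as a named field with the
value used throughout the analysis, so that each filtering rule is explicit
and auditable. All parameters can be overridden from a YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidConfigError

# Arena geometry (mm). The circular track is an annulus; linearized position
# lives on its midline circle.
OUTER_DIAMETER_MM = 325.0
TRACK_WIDTH_MM = 50.0


def midline_circumference_cm(
    outer_diameter_mm: float = OUTER_DIAMETER_MM,
    track_width_mm: float = TRACK_WIDTH_MM,
) -> float:
    """Circumference of the annulus midline, in cm.

    (outer diameter - track width) is the midline diameter: 325 - 50 = 275 mm,
    giving C = pi * 27.5 cm = 86.39 cm.
    """
    return float((outer_diameter_mm - track_width_mm) / 10.0 * 3.141592653589793)


@dataclass
class AnalysisParams:
    """All tunable thresholds of the analysis, with their default values.

    Attributes
    ----------
    speed_threshold_mm_s:
        Frames count as "moving" only when speed strictly exceeds this.
    bin_size_cm:
        Spatial bin size, both for 1D (linear) and 2D (square) bins.
    boxcar_bins:
        Width of the circular boxcar used to smooth 1D rate maps.
    gaussian_sigma_bins:
        Standard deviation (in bins) of the 2D Gaussian smoothing kernel.
    n_shuffles, shuffle_percentile:
        Size of the shuffle null and the chance criterion: a cell's spatial
        information must exceed this percentile of the null.
    field_threshold:
        Fraction of the map maximum defining place-field membership.
    lap_fraction:
        1D criterion 1: minimum fraction of complete laps with an in-field
        event.
    infield_event_fraction_1d / _2d:
        Criterion 2: minimum fraction of moving in-field frames containing an
        event (5% on the track, 2% in the open field).
    max_gap_s:
        Tracking gaps longer than this invalidate the imaging frames they
        span.
    speed_median_frames:
        Window of the median filter applied to frame-rate speed before gating.
    variance_threshold:
        Cumulative-variance criterion defining manifold dimensionality.
    k_folds:
        Cross-validation folds for position decoding.
    retention_cm:
        Maximum circular field shift still counted as "retained location".
    shuffle_mode:
        "permute" scatters per-frame activity values over moving frames;
        "rotate" applies a random circular shift instead.
    lap_event_scope:
        "field" requires the per-lap event to fall inside the detected field
        (criterion 1); "anywhere" accepts any event during the lap.
    """

    speed_threshold_mm_s: float = 20.0
    bin_size_cm: float = 2.0
    boxcar_bins: int = 3
    gaussian_sigma_bins: float = 1.5
    n_shuffles: int = 1000
    shuffle_percentile: float = 99.0
    field_threshold: float = 0.5
    lap_fraction: float = 0.5
    infield_event_fraction_1d: float = 0.05
    infield_event_fraction_2d: float = 0.02
    max_gap_s: float = 0.5
    speed_median_frames: int = 5
    variance_threshold: float = 0.9
    k_folds: int = 5
    retention_cm: float = 2.0
    shuffle_mode: str = "permute"
    lap_event_scope: str = "field"
    circumference_cm: float = field(default_factory=midline_circumference_cm)
    arena_diameter_mm: float = OUTER_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.speed_threshold_mm_s < 0:
            raise InvalidConfigError("speed threshold must be >= 0")
        if self.bin_size_cm <= 0:
            raise InvalidConfigError("bin size must be positive")
        if self.n_shuffles < 1:
            raise InvalidConfigError("need at least one shuffle")
        if not 0 < self.field_threshold < 1:
            raise InvalidConfigError("field threshold must be in (0, 1)")
        if self.shuffle_mode not in ("permute", "rotate"):
            raise InvalidConfigError(f"unknown shuffle_mode {self.shuffle_mode!r}")
        if self.lap_event_scope not in ("field", "anywhere"):
            raise InvalidConfigError(
                f"unknown lap_event_scope {self.lap_event_scope!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown analysis keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
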