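"""Per-well projected-area time series and their normalised form.

The primary readout of a spheroid-formation assay is the projected area
occupied by the cells in each well, sampled on a regular (30-min) grid.
:class:`AreaTrajectory` holds the raw areas (with missing frames recorded as
NaN and flagged, e.g. when a spheroid left the field of view or segmentation
found no object); :class:`NormalizedTrajectory` holds the same series divided
by its value at time 0 h (NA, normalised area).

Both round-trip through a flat CSV layout with columns
``well_id, frame, time_h, area, missing_flag`` so cohorts from many wells can
live in a single file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AreaTrajectory",
    "NormalizedTrajectory",
    "read_trajectories_csv",
    "write_trajectories_csv",
]


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class AreaTrajectory:
    """Projected area of one well over time.

    Parameters
    ----------
    well_id : str
        Identifier of the well (or simulated run).
    times_h : array of float
        Acquisition time of each frame in hours, uniformly spaced.
    areas : array of float
        Projected area per frame (µm², or px² / arbitrary units when the
        pixel size is unknown). NaN where the frame is missing.
    missing : array of bool
        True where no area could be measured for the frame.
    interpolated : array of bool, optional
        True where the value was filled in by interpolation.
    interval_minutes : float
        Frame interval; 30 min in the assays this package emulates.
    """

    well_id: str
    times_h: np.ndarray
    areas: np.ndarray
    missing: np.ndarray | None = None
    interpolated: np.ndarray | None = None
    interval_minutes: float = 30.0

    def __post_init__(self) -> None:
        self.times_h = _as_float_array(self.times_h)
        self.areas = _as_float_array(self.areas)
        if self.missing is None:
            self.missing = np.isnan(self.areas)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.areas.shape, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = len(self.areas)
        if not (len(self.times_h) == len(self.missing) == len(self.interpolated) == n):
            raise ValueError("times_h, areas and flag arrays must share one length")
        if self.interval_minutes <= 0:
            raise ValueError("interval_minutes must be positive")
        valid = ~self.missing
        if np.any(self.areas[valid] < 0):
            raise ValueError("areas must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.areas)

    def copy(self) -> "AreaTrajectory":
        return replace(
            self,
            times_h=self.times_h.copy(),
            areas=self.areas.copy(),
            missing=self.missing.copy(),
            interpolated=self.interpolated.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_id": self.well_id,
                "frame": np.arange(self.n_frames),
                "time_h": self.times_h,
                "area": self.areas,
                "missing_flag": self.missing.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, interval_minutes: float | None = None) -> "AreaTrajectory":
        df = df.sort_values("frame")
        well = str(df["well_id"].iloc[0])
        times = df["time_h"].to_numpy(dtype=float)
        if interval_minutes is None:
            interval_minutes = 60.0 * (times[1] - times[0]) if len(times) > 1 else 30.0
        return cls(
            well_id=well,
            times_h=times,
            areas=df["area"].to_numpy(dtype=float),
            missing=df["missing_flag"].to_numpy(dtype=bool),
            interval_minutes=float(interval_minutes),
        )


@dataclass
class NormalizedTrajectory:
    """Area trajectory normalised to the frame-0 area (NA).

    ``na[0] == 1`` exactly; values are unitless. ``interpolated`` marks
    frames whose underlying area was filled in rather than measured.
    """

    well_id: str
    times_h: np.ndarray
    na: np.ndarray
    interpolated: np.ndarray | None = None
    interval_minutes: float = 30.0

    def __post_init__(self) -> None:
        self.times_h = _as_float_array(self.times_h)
        self.na = _as_float_array(self.na)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.na.shape, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if len(self.times_h) != len(self.na) or len(self.na) != len(self.interpolated):
            raise ValueError("times_h, na and interpolated must share one length")
        if len(self.na) == 0 or not np.isclose(self.na[0], 1.0):
            raise ValueError("normalised trajectories must start at NA = 1")
        finite = np.isfinite(self.na)
        if np.any(self.na[finite] <= 0):
            raise ValueError("normalised areas must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.na)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_id": self.well_id,
                "frame": np.arange(self.n_frames),
                "time_h": self.times_h,
                "na": self.na,
                "interpolated_flag": self.interpolated.astype(int),
            }
        )


def write_trajectories_csv(trajectories: Iterable[AreaTrajectory], path: str | Path) -> None:
    """Write one or more trajectories to a single long-format CSV."""
    frames = [t.to_frame() for t in trajectories]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories_csv(path: str | Path) -> list[AreaTrajectory]:
    """Read every well found in a long-format trajectory CSV."""
    df = pd.read_csv(path)
    required = {"well_id", "frame", "time_h", "area", "missing_flag"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    return [AreaTrajectory.from_frame(sub) for _, sub in df.groupby("well_id", sort=True)]
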