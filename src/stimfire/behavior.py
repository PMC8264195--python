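"""Open-field and elevated-plus-maze metrics from tracked 2-D trajectories.

The open field is a 40 cm square separated into a central and a peripheral
zone; the elevated plus maze has two open and two closed arms (15 cm wide,
45 cm long) joined by a central platform.  Anxiety-related metrics are
occupancy times, entries, and path lengths per zone, computed from the
centroid trajectory exactly as a video-tracking system would export it:
samples ``(t_s, x_cm, y_cm)``.

Conventions (all configurable where meaningful):

* the time interval between consecutive samples is attributed to the zone
  of the interval's first sample, so zone times partition the session;
* segment path length is attributed to the zone of the segment's start;
* an entry is a maximal run of in-zone samples of at least ``dwell_min``
  samples (a session that starts inside the zone counts as one entry);
* an EPM arm entry additionally requires the centroid to penetrate a
  configurable ingress depth (default 5 cm) into the arm, a centroid proxy
  for the four-paw criterion used with video scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ValidationError

__all__ = [
    "ArenaGeometry",
    "Trajectory",
    "BehaviorConfig",
    "OftMetrics",
    "EpmMetrics",
    "oft_metrics",
    "epm_metrics",
]

OPEN_FIELD = "open_field"
ELEVATED_PLUS_MAZE = "elevated_plus_maze"


@dataclass(frozen=True)
class ArenaGeometry:
    """Zone geometry of one apparatus.

    Open field: a ``side_cm`` square ``[0, side] x [0, side]`` whose central
    zone is a concentric square with linear fraction ``center_fraction``
    (the published apparatus marks the central region with lines but not its
    size; 50% linear is the default and is configurable).

    Elevated plus maze: arms of ``arm_width_cm`` x ``arm_length_cm`` around
    a ``arm_width_cm`` square central platform centred at the origin; the
    open arms run along ``open_arm_axis`` ("x" or "y").
    """

    kind: str
    side_cm: float = 40.0
    center_fraction: float = 0.5
    arm_width_cm: float = 15.0
    arm_length_cm: float = 45.0
    open_arm_axis: str = "x"

    def __post_init__(self):
        if self.kind not in (OPEN_FIELD, ELEVATED_PLUS_MAZE):
            raise InvalidParameterError(f"unknown arena kind {self.kind!r}")
        if self.kind == OPEN_FIELD and not (0 < self.center_fraction < 1):
            raise InvalidParameterError("center_fraction must be in (0, 1)")
        if self.open_arm_axis not in ("x", "y"):
            raise InvalidParameterError("open_arm_axis must be 'x' or 'y'")

    @classmethod
    def open_field(cls, side_cm: float = 40.0, center_fraction: float = 0.5) -> "ArenaGeometry":
        return cls(kind=OPEN_FIELD, side_cm=side_cm, center_fraction=center_fraction)

    @classmethod
    def elevated_plus_maze(
        cls,
        arm_width_cm: float = 15.0,
        arm_length_cm: float = 45.0,
        open_arm_axis: str = "x",
    ) -> "ArenaGeometry":
        return cls(
            kind=ELEVATED_PLUS_MAZE,
            arm_width_cm=arm_width_cm,
            arm_length_cm=arm_length_cm,
            open_arm_axis=open_arm_axis,
        )

    # -- open-field helpers -------------------------------------------------
    @property
    def center_bounds(self) -> tuple[float, float]:
        """Low/high coordinate of the central square (both axes)."""
        margin = self.side_cm * (1 - self.center_fraction) / 2
        return margin, self.side_cm - margin

    # -- shared interface ---------------------------------------------------
    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == OPEN_FIELD:
            s = self.side_cm
            return (x >= 0) & (x <= s) & (y >= 0) & (y <= s)
        half_w = self.arm_width_cm / 2
        reach = half_w + self.arm_length_cm
        in_x_bar = (np.abs(y) <= half_w) & (np.abs(x) <= reach)
        in_y_bar = (np.abs(x) <= half_w) & (np.abs(y) <= reach)
        return in_x_bar | in_y_bar

    def zone_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Zone label per sample.

        Open field: ``center`` / ``periphery``.  EPM: ``center`` (platform),
        ``open_arm``, ``closed_arm``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == OPEN_FIELD:
            lo, hi = self.center_bounds
            inside = (x >= lo) & (x <= hi) & (y >= lo) & (y <= hi)
            return np.where(inside, "center", "periphery")
        half_w = self.arm_width_cm / 2
        on_platform = (np.abs(x) <= half_w) & (np.abs(y) <= half_w)
        along_open = np.abs(x) > half_w if self.open_arm_axis == "x" else np.abs(y) > half_w
        return np.where(on_platform, "center", np.where(along_open, "open_arm", "closed_arm"))

    def arm_depth(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Penetration depth (cm) past the platform edge into whichever arm; 0 on the platform."""
        if self.kind != ELEVATED_PLUS_MAZE:
            raise InvalidParameterError("arm_depth is only defined for the plus maze")
        half_w = self.arm_width_cm / 2
        depth = np.maximum(np.abs(np.asarray(x, float)), np.abs(np.asarray(y, float))) - half_w
        return np.maximum(depth, 0.0)


@dataclass(frozen=True)
class Trajectory:
    """Timed centroid positions (seconds, centimetres)."""

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t_s, dtype=float)
        x = np.asarray(self.x_cm, dtype=float)
        y = np.asarray(self.y_cm, dtype=float)
        for name, arr in (("t_s", t), ("x_cm", x), ("y_cm", y)):
            object.__setattr__(self, name, arr)
        if not (t.size == x.size == y.size):
            raise ValidationError("t/x/y must have equal length")
        if t.size < 2:
            raise ValidationError("a trajectory needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValidationError("sample times must be strictly increasing", row=bad, column="t_s")

    @property
    def n_samples(self) -> int:
        return int(self.t_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "x_cm": self.x_cm, "y_cm": self.y_cm})


@dataclass(frozen=True)
class BehaviorConfig:
    """Scoring parameters: minimum dwell per entry and EPM ingress depth."""

    dwell_min_samples: int = 1
    arm_ingress_depth_cm: float = 5.0


@dataclass(frozen=True)
class OftMetrics:
    center_time_s: float
    center_distance_m: float
    center_entries: int
    total_distance_m: float
    zone_crossings: int
    duration_s: float


@dataclass(frozen=True)
class EpmMetrics:
    open_arm_time_s: float
    open_arm_time_pct: float
    open_arm_entries: int
    closed_arm_time_s: float
    center_time_s: float
    total_distance_m: float
    duration_s: float


def _check_inside(traj: Trajectory, geometry: ArenaGeometry) -> None:
    ok = geometry.contains(traj.x_cm, traj.y_cm)
    if not np.all(ok):
        bad = int(np.argmax(~ok))
        raise ValidationError(
            f"sample at t={traj.t_s[bad]:.3f}s is outside the arena "
            f"({traj.x_cm[bad]:.2f}, {traj.y_cm[bad]:.2f})",
            row=bad,
        )


def _interval_weights(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample dwell times and per-segment path lengths (both length n-1)."""
    dt = np.diff(traj.t_s)
    seg = np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm))
    return dt, seg


def _entries(in_zone: np.ndarray, dwell_min: int) -> int:
    """Number of maximal in-zone runs of at least ``dwell_min`` samples."""
    padded = np.concatenate([[False], in_zone.astype(bool), [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    return int(np.sum((ends - starts) >= dwell_min))


def oft_metrics(
    traj: Trajectory, geometry: ArenaGeometry | None = None, config: BehaviorConfig | None = None
) -> OftMetrics:
    """Open-field metrics: central-zone time, distance, entries; totals; crossings."""
    geometry = geometry or ArenaGeometry.open_field()
    if geometry.kind != OPEN_FIELD:
        raise InvalidParameterError("oft_metrics needs an open-field geometry")
    config = config or BehaviorConfig()
    _check_inside(traj, geometry)

    zones = geometry.zone_of(traj.x_cm, traj.y_cm)
    in_center = zones == "center"
    dt, seg = _interval_weights(traj)
    start_in_center = in_center[:-1]

    return OftMetrics(
        center_time_s=float(dt[start_in_center].sum()),
        center_distance_m=float(seg[start_in_center].sum()) / 100.0,
        center_entries=_entries(in_center, config.dwell_min_samples),
        total_distance_m=float(seg.sum()) / 100.0,
        zone_crossings=int(np.sum(zones[1:] != zones[:-1])),
        duration_s=traj.duration_s,
    )


def epm_metrics(
    traj: Trajectory, geometry: ArenaGeometry | None = None, config: BehaviorConfig | None = None
) -> EpmMetrics:
    """Elevated-plus-maze metrics: open-arm time, percent time, and entries."""
    geometry = geometry or ArenaGeometry.elevated_plus_maze()
    if geometry.kind != ELEVATED_PLUS_MAZE:
        raise InvalidParameterError("epm_metrics needs a plus-maze geometry")
    config = config or BehaviorConfig()
    _check_inside(traj, geometry)

    zones = geometry.zone_of(traj.x_cm, traj.y_cm)
    dt, seg = _interval_weights(traj)
    open_time = float(dt[(zones == "open_arm")[:-1]].sum())
    closed_time = float(dt[(zones == "closed_arm")[:-1]].sum())
    center_time = float(dt[(zones == "center")[:-1]].sum())
    duration = traj.duration_s

    deep = geometry.arm_depth(traj.x_cm, traj.y_cm) >= config.arm_ingress_depth_cm
    deep_open = (zones == "open_arm") & deep
    # an entry requires leaving the arm entirely before it can be recounted:
    # count transitions where a deep-open sample is first reached since the
    # last time the animal was off the open arms.
    entries = 0
    armed = True
    for on_arm, is_deep in zip(zones == "open_arm", deep_open):
        if not on_arm:
            armed = True
        elif is_deep and armed:
            entries += 1
            armed = False

    return EpmMetrics(
        open_arm_time_s=open_time,
        open_arm_time_pct=100.0 * open_time / duration if duration else 0.0,
        open_arm_entries=entries,
        closed_arm_time_s=closed_time,
        center_time_s=center_time,
        total_distance_m=float(seg.sum()) / 100.0,
        duration_s=duration,
    )
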