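"""Core data containers: force-plate records, COP trajectories, trials.

Unit conventions, used throughout the package:

* marker positions, COP positions and task geometry are in **millimetres**
  in a right-handed lab frame (x forward, y left, z up), time zero at the
  first sample, 0-based sample indexing;
* force-plate channels are in **newtons** (forces) and **newton-metres**
  (moments about the plate origin); plate geometry/pose is in **metres**.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "ForcePlateRecord",
    "CopTrajectory",
    "TrialRecord",
    "TaskGeometry",
    "TargetError",
]


def _as_channel(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ParameterError(f"channel {name!r} must be one-dimensional")
    return arr


@dataclass
class ForcePlateRecord:
    """One force plate's force/moment time series plus geometry and pose.

    ``fx, fy, fz`` are lab-vertical-aligned plate-frame forces in N sampled at
    ``rate`` Hz; ``mx, my, mz`` are moments about the plate origin in N·m.
    ``origin`` (m) and ``yaw`` (rad, about vertical) place the plate in the lab
    frame; ``z0`` is the offset of the true contact surface above the plate
    origin (m).
    """

    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray
    rate: float = 1000.0
    plate_size: tuple = (0.90, 0.60)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    yaw: float = 0.0
    z0: float = 0.0
    label: str = ""

    def __post_init__(self):
        for name in ("fx", "fy", "fz", "mx", "my", "mz"):
            setattr(self, name, _as_channel(getattr(self, name), name))
        n = len(self.fz)
        for name in ("fx", "fy", "fz", "mx", "my", "mz"):
            if len(getattr(self, name)) != n:
                raise ParameterError("all force/moment channels must have equal length")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if not (self.plate_size[0] > 0 and self.plate_size[1] > 0):
            raise ParameterError("plate_size must be positive")
        if abs(self.z0) >= 0.2:
            raise ParameterError("surface offset z0 must satisfy |z0| < 0.2 m")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def n_samples(self) -> int:
        return len(self.fz)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


@dataclass
class CopTrajectory:
    """Planar lab-frame center-of-pressure time series in millimetres.

    ``valid`` masks samples where the COP is defined (enough vertical load);
    invalid samples are excluded from every temporal average downstream.
    ``provenance`` records whether the trajectory comes from a single foot or
    from combining two feet. ``fz`` optionally carries the vertical load used,
    enabling force-weighted combination.
    """

    xy: np.ndarray
    rate: float
    valid: np.ndarray
    provenance: str = "single"
    fz: Optional[np.ndarray] = None

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ParameterError("xy must have shape (n, 2)")
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)
        if len(self.valid) != len(self.xy):
            raise ParameterError("valid mask must match xy length")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if self.provenance not in ("single", "combined"):
            raise ParameterError("provenance must be 'single' or 'combined'")
        if self.fz is not None:
            self.fz = np.asarray(self.fz, dtype=float).reshape(-1)
            if len(self.fz) != len(self.xy):
                raise ParameterError("fz must match xy length")
        if not np.all(np.isfinite(self.xy[self.valid])):
            raise ParameterError("valid samples must be finite")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_xy(self) -> np.ndarray:
        return self.xy[self.valid]


@dataclass
class TaskGeometry:
    """Lab-frame geometry of the three motor tasks.

    The balance beam is represented by its centreline segment (the physical
    beam is 5 cm wide, 5 cm high, 5 m long); precision jumps by the target
    line segment and the required jump distance (90 cm double-leg, 40 cm
    single-leg). All coordinates in mm.
    """

    beam_line: np.ndarray = field(
        default_factory=lambda: np.array([[-2500.0, 0.0], [2500.0, 0.0]])
    )
    jump_target_line: np.ndarray = field(
        default_factory=lambda: np.array([[-300.0, 0.0], [300.0, 0.0]])
    )
    jump_distance_double_mm: float = 900.0
    jump_distance_single_mm: float = 400.0
    beam_width_mm: float = 50.0
    beam_height_mm: float = 50.0

    def __post_init__(self):
        self.beam_line = np.asarray(self.beam_line, dtype=float).reshape(2, 2)
        self.jump_target_line = np.asarray(
            self.jump_target_line, dtype=float
        ).reshape(2, 2)
        for name in ("beam_line", "jump_target_line"):
            seg = getattr(self, name)
            if np.allclose(seg[0], seg[1]):
                raise ParameterError(f"{name} must have nonzero length")


#: canonical task names for the motor outcomes
MOTOR_TASKS = ("balance", "one_leg_stand", "precision_jump")


@dataclass
class TargetError:
    """One scalar motor outcome per trial; lower values mean better performance."""

    value: float
    task: str
    side: str = ""
    n_valid_samples: int = 0
    unit: str = "mm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.value < 0:
            raise ParameterError("target error must be non-negative")
        if self.task not in MOTOR_TASKS:
            raise ParameterError(f"unknown task {self.task!r}")


@dataclass
class TrialRecord:
    """Marker + force data for one task execution.

    ``markers`` maps marker labels to (n, 3) mm trajectories at
    ``marker_rate`` Hz; ``plates`` holds the force-plate records involved in
    the trial. Keyed by subject/group/time/task/side/trial index.
    """

    subject: str
    group: str
    time: str
    task: str
    side: str
    trial_index: int
    markers: dict = field(default_factory=dict)
    marker_rate: float = 200.0
    plates: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in MOTOR_TASKS:
            raise ParameterError(f"unknown task {self.task!r}")
        for name, traj in self.markers.items():
            arr = np.asarray(traj, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ParameterError(f"marker {name!r} must have shape (n, 3)")
            self.markers[name] = arr

    @property
    def key(self) -> tuple:
        return (self.subject, self.time, self.task, self.side, self.trial_index)
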