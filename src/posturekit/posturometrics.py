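"""COP trajectories and task-specific target-error metrics.

The center of pressure (COP) is the point of application of the resultant
ground reaction force on the plate surface. With forces (Fx, Fy, Fz) and
moments (Mx, My, Mz) about the plate origin, and a contact surface offset
z0 above that origin, static moment balance gives, in the plate frame::

    COPx = (-My - Fx * z0) / Fz
    COPy = ( Mx - Fy * z0) / Fz

Samples carrying less than ``min_load`` of vertical force are masked invalid
instead of being divided through, which prevents the COP from blowing up as
Fz -> 0 (e.g. between beam contacts or before a jump landing).

All three motor outcomes are distances in millimetres, lower = better:

* balance beam: temporal average of the perpendicular distance from the COP
  to the beam centreline;
* one-leg stand: temporal average of the distance from the COP to the
  barycenter (time-average position) of its own trajectory;
* precision jump: horizontal distance from the big-toe marker at the time of
  landing to the target line.
"""

from __future__ import annotations

import numpy as np

from .exceptions import (
    AlignmentError,
    EmptyTrajectoryError,
    MetricError,
    NoLandingError,
    ParameterError,
)
from .types import CopTrajectory, ForcePlateRecord, TargetError, TaskGeometry

__all__ = [
    "compute_cop_single",
    "combine_cop",
    "balance_beam_error",
    "one_leg_stand_error",
    "detect_landing",
    "precision_jump_error",
]


def compute_cop_single(
    plate: ForcePlateRecord, min_load: float = 10.0, label: str = ""
) -> CopTrajectory:
    """Moment-balance COP of a single foot on one plate, in lab-frame mm.

    Inputs are assumed conditioned (hum removed, low-pass applied). Samples
    with Fz below ``min_load`` N are masked invalid; if every sample is below
    the threshold an :class:`EmptyTrajectoryError` naming the trial is raised.
    """
    if min_load <= 0:
        raise ParameterError("min_load must be positive")
    fz = plate.fz
    valid = fz >= min_load
    if not valid.any():
        raise EmptyTrajectoryError(
            f"trial {label or plate.label or '<unnamed>'}: no sample reaches "
            f"the minimum vertical load of {min_load:g} N"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        copx_p = (-plate.my - plate.fx * plate.z0) / fz
        copy_p = (plate.mx - plate.fy * plate.z0) / fz
    c, s = np.cos(plate.yaw), np.sin(plate.yaw)
    lab_x = plate.origin[0] + c * copx_p - s * copy_p
    lab_y = plate.origin[1] + s * copx_p + c * copy_p
    xy = np.column_stack([lab_x, lab_y]) * 1000.0  # m -> mm
    xy[~valid] = np.nan
    return CopTrajectory(xy=xy, rate=plate.rate, valid=valid, provenance="single", fz=fz)


def combine_cop(
    left: CopTrajectory, right: CopTrajectory, mode: str = "unweighted"
) -> CopTrajectory:
    """Combine the COPs of two feet into one trajectory.

    ``unweighted`` (the default) takes the per-sample spatial average of the
    two COPs where both are valid; ``force_weighted`` weights each foot by its
    vertical load. Where only one foot is valid its COP is used; where neither
    is, the sample is invalid.
    """
    if mode not in ("unweighted", "force_weighted"):
        raise ParameterError("mode must be 'unweighted' or 'force_weighted'")
    if left.rate != right.rate or len(left.xy) != len(right.xy):
        raise AlignmentError(
            "left and right COP trajectories must share rate and time base "
            f"(rates {left.rate:g}/{right.rate:g}, lengths "
            f"{len(left.xy)}/{len(right.xy)})"
        )
    n = len(left.xy)
    xy = np.full((n, 2), np.nan)
    both = left.valid & right.valid
    only_l = left.valid & ~right.valid
    only_r = right.valid & ~left.valid
    if mode == "force_weighted":
        if left.fz is None or right.fz is None:
            raise ParameterError("force_weighted combination requires fz on both trajectories")
        wl = np.clip(left.fz, 0, None)
        wr = np.clip(right.fz, 0, None)
        tot = wl + wr
        safe = both & (tot > 0)
        xy[safe] = (
            wl[safe, None] * left.xy[safe] + wr[safe, None] * right.xy[safe]
        ) / tot[safe, None]
        both = safe
    else:
        xy[both] = 0.5 * (left.xy[both] + right.xy[both])
    xy[only_l] = left.xy[only_l]
    xy[only_r] = right.xy[only_r]
    valid = both | only_l | only_r
    fz = None
    if left.fz is not None and right.fz is not None:
        fz = np.clip(left.fz, 0, None) + np.clip(right.fz, 0, None)
    return CopTrajectory(xy=xy, rate=left.rate, valid=valid, provenance="combined", fz=fz)


def _segment_distance(points: np.ndarray, segment: np.ndarray):
    """Distance from 2D points to a line segment; beyond the endpoints the
    distance to the nearest endpoint is used. Returns (distances, beyond)."""
    a, b = np.asarray(segment, dtype=float)
    d = b - a
    L2 = float(d @ d)
    if L2 <= 0:
        raise ParameterError("segment must have nonzero length")
    t = (points - a) @ d / L2
    t_clip = np.clip(t, 0.0, 1.0)
    proj = a + t_clip[:, None] * d
    dist = np.linalg.norm(points - proj, axis=1)
    beyond = (t < 0.0) | (t > 1.0)
    return dist, beyond


def balance_beam_error(
    cop: CopTrajectory, geometry: TaskGeometry, side: str = ""
) -> TargetError:
    """Mean perpendicular distance (mm) from valid COP samples to the beam
    centreline."""
    pts = cop.valid_xy()
    if len(pts) < 1:
        raise MetricError("balance beam error needs at least one valid COP sample")
    dist, beyond = _segment_distance(pts, geometry.beam_line)
    return TargetError(
        value=float(dist.mean()),
        task="balance",
        side=side,
        n_valid_samples=len(pts),
        meta={"n_beyond_segment": int(beyond.sum())},
    )


def one_leg_stand_error(cop: CopTrajectory, side: str = "") -> TargetError:
    """Mean distance (mm) of valid COP samples from the trajectory barycenter."""
    pts = cop.valid_xy()
    if len(pts) < 2:
        raise MetricError("one-leg-stand error needs at least two valid COP samples")
    barycenter = pts.mean(axis=0)
    dist = np.linalg.norm(pts - barycenter, axis=1)
    return TargetError(
        value=float(dist.mean()),
        task="one_leg_stand",
        side=side,
        n_valid_samples=len(pts),
        meta={"barycenter_mm": barycenter.tolist()},
    )


def detect_landing(
    plate: ForcePlateRecord, threshold: float = 20.0, hold_ms: float = 20.0
) -> float:
    """First time (s) the vertical force exceeds ``threshold`` N and stays
    above it for ``hold_ms`` milliseconds. Brief spikes shorter than the hold
    window are rejected."""
    if threshold <= 0 or hold_ms <= 0:
        raise ParameterError("threshold and hold_ms must be positive")
    h = max(1, int(round(hold_ms / 1000.0 * plate.rate)))
    above = plate.fz >= threshold
    if len(above) < h or not above.any():
        raise NoLandingError(
            f"vertical force never sustains {threshold:g} N for {hold_ms:g} ms"
        )
    sustained = np.convolve(above.astype(int), np.ones(h, dtype=int), mode="valid") == h
    idx = np.flatnonzero(sustained)
    if len(idx) == 0:
        raise NoLandingError(
            f"vertical force never sustains {threshold:g} N for {hold_ms:g} ms"
        )
    return float(idx[0] / plate.rate)


def precision_jump_error(
    toe: np.ndarray,
    rate: float,
    geometry: TaskGeometry,
    landing_time: float,
    side: str = "",
    search_ms: float = 25.0,
) -> TargetError:
    """Horizontal-plane distance (mm) from the big-toe marker at landing time
    to the jump target line.

    If the toe sample at ``landing_time`` is invalid (non-finite), the nearest
    valid sample within ``search_ms`` is used; with none available a
    :class:`MetricError` is raised. Landings beyond the lateral extent of the
    target segment score the distance to the nearest endpoint and are flagged
    in the metadata.
    """
    toe = np.asarray(toe, dtype=float)
    if toe.ndim != 2 or toe.shape[1] != 3:
        raise ParameterError("toe trajectory must have shape (n, 3)")
    n = len(toe)
    idx = int(round(landing_time * rate))
    if idx < 0 or idx >= n:
        raise MetricError(
            f"landing time {landing_time:g} s is outside the toe trajectory"
        )
    finite = np.all(np.isfinite(toe[:, :2]), axis=1)
    use = idx
    if not finite[idx]:
        radius = max(1, int(round(search_ms / 1000.0 * rate)))
        lo, hi = max(0, idx - radius), min(n, idx + radius + 1)
        cand = np.flatnonzero(finite[lo:hi])
        if len(cand) == 0:
            raise MetricError(
                f"no valid toe sample within {search_ms:g} ms of landing at "
                f"{landing_time:g} s"
            )
        use = lo + cand[np.argmin(np.abs(cand + lo - idx))]
    point = toe[use, :2][None, :]
    dist, beyond = _segment_distance(point, geometry.jump_target_line)
    return TargetError(
        value=float(dist[0]),
        task="precision_jump",
        side=side,
        n_valid_samples=1,
        meta={
            "beyond_segment": bool(beyond[0]),
            "sample_used": int(use),
            "landing_time_s": float(landing_time),
        },
    )
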