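"""Rigid-rotation comparison of conformational states.

Differences between conformational states of a rotary enzyme are summarized
as rigid-body motions: a least-squares superposition of matched Cα sets
gives a proper rigid transform, whose rotation part is reported as an angle
about a screw axis placed in space (not through the origin).  For a ring
with n-fold symmetry the rotational offset between two states is only
defined modulo 360/n degrees, so the ring comparison first matches subunits
by the best circular relabelling and then reports the residual angle in
(−180/n, +180/n].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .helix_geometry import BackboneModel
from .map_ops import RigidTransform

__all__ = [
    "StateRotation",
    "RingSpec",
    "superpose",
    "rotation_angle_axis",
    "ring_offset",
    "interpolate_states",
]

ANGLE_UNDEFINED_BELOW = 0.1  # degrees: no meaningful axis below this


@dataclass
class StateRotation:
    """Angle/axis summary of an inter-state rigid motion."""

    angle: float                 # degrees in [0, 180]
    axis: np.ndarray | None      # unit vector; None when angle ~ 0
    axis_point: np.ndarray | None
    rmsd_before: float = float("nan")
    rmsd_after: float = float("nan")

    @property
    def axis_defined(self) -> bool:
        return self.axis is not None

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle,
            "axis": None if self.axis is None else list(self.axis),
            "axis_point": None if self.axis_point is None else list(self.axis_point),
            "rmsd_before": self.rmsd_before,
            "rmsd_after": self.rmsd_after,
        }


@dataclass(frozen=True)
class RingSpec:
    """Ring symmetry description: n-fold order plus axis (point + direction)."""

    symmetry_order: int = 8
    axis_point: tuple = (0.0, 0.0, 0.0)
    axis_dir: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.symmetry_order < 1:
            raise ValueError("symmetry_order must be >= 1")


def _as_points(model) -> np.ndarray:
    if isinstance(model, BackboneModel):
        return model.ca
    return np.asarray(model, dtype=float)


def superpose(model_a, model_b) -> tuple[RigidTransform, float, float]:
    """Least-squares proper superposition of matched Cα sets (a onto b).

    Returns (transform, rmsd_before, rmsd_after); reflections are excluded.
    """
    pa = _as_points(model_a)
    pb = _as_points(model_b)
    if pa.shape != pb.shape:
        raise ValueError("point sets must have equal shapes")
    if len(pa) < 3:
        raise ValueError("superposition needs at least 3 points")
    ca_ = pa.mean(axis=0)
    cb_ = pb.mean(axis=0)
    a0 = pa - ca_
    b0 = pb - cb_
    if np.linalg.matrix_rank(np.vstack([a0, b0]), tol=1e-8) < 2:
        raise ValueError("collinear or coincident point sets: rotation ill-defined")
    rot_obj, _ = Rotation.align_vectors(b0, a0)
    rot = rot_obj.as_matrix()
    trans = cb_ - rot @ ca_
    t = RigidTransform(rot, trans)
    rmsd_before = float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
    moved = t.apply(pa)
    rmsd_after = float(np.sqrt(np.mean(np.sum((moved - pb) ** 2, axis=1))))
    return t, rmsd_before, rmsd_after


def rotation_angle_axis(t: RigidTransform,
                        reference_point: np.ndarray | None = None) -> StateRotation:
    """Decompose a rigid transform into rotation angle and screw axis.

    ``reference_point`` (default origin) selects, among the points of the
    screw axis, the one closest to it — typically the centroid of the moving
    set, so the axis is drawn where the motion happens.
    """
    rot_obj = Rotation.from_matrix(t.rotation)
    rotvec = rot_obj.as_rotvec(degrees=True)
    angle = float(np.linalg.norm(rotvec))
    if angle < ANGLE_UNDEFINED_BELOW:
        return StateRotation(angle=angle, axis=None, axis_point=None)
    axis = rotvec / angle
    ref = np.zeros(3) if reference_point is None else np.asarray(reference_point, float)

    # points p on the screw axis satisfy (I - R) p = t_perp, the component of
    # the translation perpendicular to the axis
    t_perp = t.translation - (t.translation @ axis) * axis
    p, *_ = np.linalg.lstsq(np.eye(3) - t.rotation, t_perp, rcond=None)
    p = p + ((ref - p) @ axis) * axis
    return StateRotation(angle=angle, axis=axis, axis_point=p)


def describe_motion(model_a, model_b) -> StateRotation:
    """Superpose two matched states and report the rotation about its screw axis."""
    t, before, after = superpose(model_a, model_b)
    pa = _as_points(model_a)
    sr = rotation_angle_axis(t, reference_point=pa.mean(axis=0))
    sr.rmsd_before = before
    sr.rmsd_after = after
    return sr


def _angle_about_axis(pa: np.ndarray, pb: np.ndarray, point: np.ndarray,
                      direction: np.ndarray) -> tuple[float, float]:
    """Best rotation angle of a onto b about a fixed axis, plus residual RMSD."""
    u = direction / np.linalg.norm(direction)
    ra = pa - point
    rb = pb - point
    ra -= np.outer(ra @ u, u)
    rb -= np.outer(rb @ u, u)
    # maximize sum cos(theta - theta_i): theta = atan2(sum cross, sum dot)
    dot = np.sum(ra * rb)
    cross = np.sum(np.cross(ra, rb) @ u)
    theta = math.atan2(cross, dot)
    c, s = math.cos(theta), math.sin(theta)
    rot = (c * ra + s * np.cross(np.broadcast_to(u, ra.shape), ra, axis=1)
           + np.outer((1 - c) * (ra @ u), u))
    residual = float(np.sqrt(np.mean(np.sum((rot - rb) ** 2, axis=1))))
    return math.degrees(theta), residual


def ring_offset(ring_a: BackboneModel, ring_b: BackboneModel,
                spec: RingSpec = RingSpec()) -> float:
    """Rotational offset of ring_b relative to ring_a about the ring axis.

    Subunits are matched by the best circular relabelling (an n-fold ring has
    n equivalent labelings), and the result is reported modulo the symmetry
    step, in (−180/n, +180/n] degrees.
    """
    pa = _as_points(ring_a)
    pb = _as_points(ring_b)
    if pa.shape != pb.shape:
        raise ValueError("rings must have matching atom counts")
    n = spec.symmetry_order
    if len(pa) % n != 0:
        raise ValueError(f"atom count {len(pa)} not divisible by symmetry order {n}")
    per = len(pa) // n
    point = np.asarray(spec.axis_point, dtype=float)
    direction = np.asarray(spec.axis_dir, dtype=float)

    best = None
    for shift in range(n):
        rolled = np.roll(pb.reshape(n, per, 3), -shift, axis=0).reshape(-1, 3)
        theta, residual = _angle_about_axis(pa, rolled, point, direction)
        if best is None or residual < best[0]:
            best = (residual, theta)
    offset = best[1]
    step = 360.0 / n
    offset = offset - step * math.floor(offset / step + 0.5)
    if offset <= -step / 2:
        offset += step
    return float(offset)


def interpolate_states(model_a: BackboneModel, model_b: BackboneModel,
                       n_frames: int) -> list[BackboneModel]:
    """Per-atom linear interpolation between two matched states.

    For visualization only: straight-line (chord) paths, not rigid rotation
    arcs, so intermediate frames are not physically meaningful.  Endpoints
    are reproduced exactly.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if (model_a.coords.shape != model_b.coords.shape
            or not np.array_equal(model_a.numbers, model_b.numbers)):
        raise ValueError("models must have matching residues and atoms")
    frames = []
    for k in range(n_frames):
        f = k / (n_frames - 1)
        coords = (1.0 - f) * model_a.coords + f * model_b.coords
        frames.append(BackboneModel(model_a.numbers.copy(), coords))
    return frames
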