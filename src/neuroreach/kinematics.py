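"""Kinematics of the 3-DoF tabletop reach arm.

The arm is a serial chain of three revolute joints described by
Denavit-Hartenberg parameters: a vertical base rotation (J1, with link
offset ``a0`` and link length ``a1``), followed by two pitch joints
(J2, J3) forming a planar two-link mechanism of lengths ``a2`` and
``a3`` in the vertical plane selected by J1.  All lengths are in
centimetres and all angles in radians.  The end effector (EE) is the
tip of the last link.

Two coordinate frames matter:

* the **arm frame** — origin on the J1 axis at table height, z up.
  ``forward_kinematics`` and the planners work here.
* the **table (world) frame** — origin at the centre of the base
  fiducial marker (ID 0), x along the marker-0 -> marker-1 edge, y into
  the table, z up.  Perception reports targets here;
  :meth:`ArmGeometry.target_from_world` converts them for planning.

The default mounting places the J1 axis above table point (0, 30) cm,
yawed so that the arm's reachable half-plane covers the 600 x 300 mm
marker-bounded work area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon, box

__all__ = [
    "ArmGeometry",
    "JointAngles",
    "Point3D",
    "ZoneLayout",
    "Reachability",
    "UnreachableTargetError",
    "DegenerateAzimuthError",
    "dh_transform",
    "chain_transforms",
    "forward_kinematics",
    "analytic_inverse_kinematics",
    "is_reachable",
    "zone_of",
    "default_zone_layout",
]

# Servos span at most 270 degrees of travel.
_MAX_JOINT_SPAN = 1.5 * math.pi

#: Default joint limits (rad): a 270-degree window per servo, centred so
#: that the home pose (pi/2, 0, 0) and the tabletop work area are covered.
DEFAULT_JOINT_LIMITS = (
    (-math.pi / 4, 5 * math.pi / 4),
    (-3 * math.pi / 4, 3 * math.pi / 4),
    (-3 * math.pi / 4, 3 * math.pi / 4),
)


class UnreachableTargetError(ValueError):
    """Raised when a requested EE target cannot be attained."""


class DegenerateAzimuthError(ValueError):
    """Raised for targets on the vertical J1 axis, where the base azimuth
    is undefined."""


@dataclass(frozen=True)
class Point3D:
    """A 3-D coordinate triple in centimetres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("Point3D coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "Point3D":
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class JointAngles:
    """Joint angles (rad) for the three revolute joints."""

    theta1: float
    theta2: float
    theta3: float

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v) for v in (self.theta1, self.theta2, self.theta3)
        ):
            raise ValueError("joint angles must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "JointAngles":
        return cls(float(a[0]), float(a[1]), float(a[2]))


#: The calibrated rest pose: arm pointing straight out, fully extended.
HOME = JointAngles(math.pi / 2, 0.0, 0.0)


@dataclass(frozen=True)
class ArmGeometry:
    """Link geometry and mounting of the arm.

    Parameters
    ----------
    a0
        Vertical offset of the J2 axis above the table (cm).
    a1, a2, a3
        Link lengths (cm).  ``a1`` is the horizontal offset introduced
        by the base joint; ``a2``/``a3`` are the upper-arm and forearm
        links of the planar pair.
    joint_limits
        Per-joint ``(min, max)`` angle in radians; each span must not
        exceed the 270-degree servo range.
    base_position
        Table-frame (x, y) of the J1 axis footprint (cm).
    base_yaw
        Rotation (rad) of the arm frame's x-axis relative to the table
        frame's x-axis about z.
    """

    a0: float = 22.0
    a1: float = 15.0
    a2: float = 13.0
    a3: float = 15.0
    joint_limits: tuple = DEFAULT_JOINT_LIMITS
    base_position: tuple = (0.0, 30.0)
    base_yaw: float = -math.pi / 2

    def __post_init__(self) -> None:
        if not (self.a1 > 0 and self.a2 > 0 and self.a3 > 0):
            raise ValueError("link lengths a1, a2, a3 must be positive")
        if self.a0 < 0:
            raise ValueError("base offset a0 must be non-negative")
        if len(self.joint_limits) != 3:
            raise ValueError("joint_limits must have three (min, max) pairs")
        for lo, hi in self.joint_limits:
            if not lo < hi:
                raise ValueError("each joint limit must satisfy min < max")
            if hi - lo > _MAX_JOINT_SPAN + 1e-12:
                raise ValueError("joint limit span exceeds the 270-degree servo range")

    # -- frame conversions -------------------------------------------------

    def world_from_arm(self, p: Point3D) -> Point3D:
        c, s = math.cos(self.base_yaw), math.sin(self.base_yaw)
        bx, by = self.base_position
        return Point3D(
            bx + c * p.x - s * p.y,
            by + s * p.x + c * p.y,
            p.z,
        )

    def target_from_world(self, p: Point3D) -> Point3D:
        """Convert a table-frame point to the arm frame for planning."""
        c, s = math.cos(self.base_yaw), math.sin(self.base_yaw)
        dx, dy = p.x - self.base_position[0], p.y - self.base_position[1]
        return Point3D(c * dx + s * dy, -s * dx + c * dy, p.z)

    def clamp(self, q: JointAngles) -> tuple:
        """Clamp angles into the joint limits.  Returns (angles, clamped?)."""
        vals = q.as_array()
        lo = np.array([l for l, _ in self.joint_limits])
        hi = np.array([h for _, h in self.joint_limits])
        clipped = np.clip(vals, lo, hi)
        changed = bool(np.any(clipped != vals))
        return JointAngles.from_array(clipped), changed

    def within_limits(self, q: JointAngles, tol: float = 1e-9) -> bool:
        for v, (lo, hi) in zip(q.as_array(), self.joint_limits):
            if v < lo - tol or v > hi + tol:
                return False
        return True

    # -- (de)serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "ArmGeometry":
        kwargs = dict(d)
        if "joint_limits" in kwargs:
            kwargs["joint_limits"] = tuple(
                tuple(float(v) for v in pair) for pair in kwargs["joint_limits"]
            )
        if "base_position" in kwargs:
            kwargs["base_position"] = tuple(float(v) for v in kwargs["base_position"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "a0": self.a0,
            "a1": self.a1,
            "a2": self.a2,
            "a3": self.a3,
            "joint_limits": [list(p) for p in self.joint_limits],
            "base_position": list(self.base_position),
            "base_yaw": self.base_yaw,
        }


# ---------------------------------------------------------------------------
# Homogeneous transforms
# ---------------------------------------------------------------------------


def dh_transform(theta: float, alpha: float, a: float, d: float) -> np.ndarray:
    """The 4x4 homogeneous transform for one DH link.

    Layout::

        [ c  -s*ca   s*sa  a*c ]
        [ s   c*ca  -c*sa  a*s ]
        [ 0     sa     ca    d ]
        [ 0      0      0    1 ]

    with ``c = cos(theta)``, ``s = sin(theta)``, ``ca = cos(alpha)``,
    ``sa = sin(alpha)``.
    """
    for name, v in (("theta", theta), ("alpha", alpha), ("a", a), ("d", d)):
        if not math.isfinite(v):
            raise ValueError(f"dh_transform: {name} must be finite, got {v!r}")
    c, s = math.cos(theta), math.sin(theta)
    ca, sa = math.cos(alpha), math.sin(alpha)
    return np.array(
        [
            [c, -s * ca, s * sa, a * c],
            [s, c * ca, -c * sa, a * s],
            [0.0, sa, ca, d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def chain_transforms(q: JointAngles, g: ArmGeometry):
    """Cumulative transforms (T01, T02, T03) from the base to each joint.

    The last column of ``T03`` is the EE position returned by
    :func:`forward_kinematics`.
    """
    t01 = dh_transform(q.theta1, math.pi / 2, g.a1, g.a0)
    t12 = dh_transform(q.theta2, 0.0, g.a2, 0.0)
    t23 = dh_transform(q.theta3, 0.0, g.a3, 0.0)
    t02 = t01 @ t12
    t03 = t02 @ t23
    return t01, t02, t03


def forward_kinematics(q: JointAngles, g: ArmGeometry) -> Point3D:
    """Arm-frame EE position for joint angles ``q``.

    Closed form (equivalent to the last column of the transform chain)::

        Px = a1*c1 + a2*c1*c2 + a3*c1*c23
        Py = a1*s1 + a2*s1*c2 + a3*s1*c23
        Pz = a0 + a2*s2 + a3*s23
    """
    c1, s1 = math.cos(q.theta1), math.sin(q.theta1)
    c2, s2 = math.cos(q.theta2), math.sin(q.theta2)
    c23 = math.cos(q.theta2 + q.theta3)
    s23 = math.sin(q.theta2 + q.theta3)
    radial = g.a1 + g.a2 * c2 + g.a3 * c23
    return Point3D(
        radial * c1,
        radial * s1,
        g.a0 + g.a2 * s2 + g.a3 * s23,
    )


# ---------------------------------------------------------------------------
# Inverse kinematics and reachability
# ---------------------------------------------------------------------------


def _planar_solutions(u: float, v: float, g: ArmGeometry):
    """Elbow branches (theta2, theta3) of the planar 2-link subproblem.

    ``(u, v)`` is the target of the a2/a3 pair: radial distance beyond
    ``a1`` and height above the J2 axis.  Yields (branch_name, t2, t3).
    """
    d2 = u * u + v * v
    denom = 2.0 * g.a2 * g.a3
    cos_t3 = (d2 - g.a2 * g.a2 - g.a3 * g.a3) / denom
    cos_t3 = min(1.0, max(-1.0, cos_t3))
    t3_mag = math.acos(cos_t3)
    for branch, t3 in (("elbow-up", -t3_mag), ("elbow-down", t3_mag)):
        t2 = math.atan2(v, u) - math.atan2(
            g.a3 * math.sin(t3), g.a2 + g.a3 * math.cos(t3)
        )
        yield branch, t2, t3


def _theta1_into_limits(phi: float, g: ArmGeometry):
    """Wrap ``phi`` by multiples of 2*pi into the J1 limit window."""
    lo, hi = g.joint_limits[0]
    for k in (-1, 0, 1):
        cand = phi + 2.0 * math.pi * k
        if lo - 1e-12 <= cand <= hi + 1e-12:
            return cand
    return None


@dataclass(frozen=True)
class Reachability:
    reachable: bool
    reason: str | None = None

    def __bool__(self) -> bool:  # allows `if is_reachable(...)`
        return self.reachable


def _annulus_ok(u: float, v: float, g: ArmGeometry) -> bool:
    d = math.hypot(u, v)
    return abs(g.a2 - g.a3) - 1e-12 <= d <= g.a2 + g.a3 + 1e-12


def is_reachable(target: Point3D, g: ArmGeometry) -> Reachability:
    """Whether some in-limit angle triple attains ``target`` (arm frame).

    The check solves the planar two-link annulus condition for both the
    direct azimuth and the mirrored azimuth (negative radial extension),
    then verifies joint limits on the candidate solutions.
    """
    r = math.hypot(target.x, target.y)
    v = target.z - g.a0
    phi = math.atan2(target.y, target.x)

    candidates = []  # (theta1, u)
    if r < 1e-12:
        # On the J1 axis: any azimuth; use the home azimuth.
        candidates.append((math.pi / 2, -g.a1))
    else:
        candidates.append((phi, r - g.a1))
        candidates.append((math.atan2(-target.y, -target.x), -r - g.a1))

    any_annulus = False
    for phi_c, u in candidates:
        if not _annulus_ok(u, v, g):
            continue
        any_annulus = True
        t1 = _theta1_into_limits(phi_c, g)
        if t1 is None:
            continue
        for _, t2, t3 in _planar_solutions(u, v, g):
            q = JointAngles(t1, t2, t3)
            if g.within_limits(q):
                return Reachability(True)
    if not any_annulus:
        return Reachability(False, "outside reach")
    return Reachability(False, "joint limits")


def analytic_inverse_kinematics(
    target: Point3D, g: ArmGeometry, branch: str = "elbow-up"
) -> JointAngles:
    """Closed-form joint angles reaching ``target`` (arm frame).

    The base azimuth is ``atan2(y, x)``; the remaining two joints solve
    the planar two-link problem in the radial-vertical plane.  ``branch``
    selects the elbow configuration: ``"elbow-up"`` (theta3 <= 0, EE
    approaches from above) or ``"elbow-down"``.

    The solution is validated by construction against the forward
    kinematics; joint limits are not enforced here (planners are
    responsible for staying within them).
    """
    if branch not in ("elbow-up", "elbow-down"):
        raise ValueError(f"unknown branch {branch!r}")
    r = math.hypot(target.x, target.y)
    if r < 1e-9:
        raise DegenerateAzimuthError(
            "target lies on the vertical base axis; azimuth undefined"
        )
    reach = is_reachable(target, g)
    if not reach:
        raise UnreachableTargetError(f"target not reachable: {reach.reason}")
    u = r - g.a1
    v = target.z - g.a0
    if not _annulus_ok(u, v, g):
        # Reachable only through the mirrored azimuth; solve there.
        phi = math.atan2(-target.y, -target.x)
        u = -r - g.a1
    else:
        phi = math.atan2(target.y, target.x)
    for name, t2, t3 in _planar_solutions(u, v, g):
        if name == branch:
            return JointAngles(phi, t2, t3)
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# Work zones
# ---------------------------------------------------------------------------


@dataclass
class ZoneLayout:
    """Named polygonal work zones partitioning the tabletop work area.

    ``zones`` maps zone ids ("Z1".."Z4") to table-frame polygons.
    Boundary points are assigned to the lowest-numbered adjacent zone.
    """

    zones: "dict[str, Polygon]"
    work_area: Polygon = field(
        default_factory=lambda: box(0.0, 0.0, 60.0, 30.0)
    )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ZoneLayout":
        zones = {
            zid: Polygon([(float(x), float(y)) for x, y in ring])
            for zid, ring in d["zones"].items()
        }
        wa = d.get("work_area")
        work_area = (
            box(*[float(v) for v in wa]) if wa else box(0.0, 0.0, 60.0, 30.0)
        )
        return cls(zones=zones, work_area=work_area)


def default_zone_layout(
    g: ArmGeometry | None = None,
    r_inner: float = 12.0,
    r_outer: float = 30.0,
    n_zones: int = 4,
    arc_steps: int = 24,
) -> ZoneLayout:
    """Equal angular sectors of the utilized reach annulus.

    The arm can theoretically reach tabletop points out to
    ``a1 + sqrt((a2+a3)^2 - a0^2)`` (~32.3 cm with the default links),
    but only an inner portion of that area is used for object
    placement; the default annulus r in [12, 30] cm is split into four
    22.5-degree sectors, numbered Z1 (smallest arm azimuth) to Z4.
    """
    g = g or ArmGeometry()
    zones: dict[str, Polygon] = {}
    sector = (math.pi / 2) / n_zones
    for i in range(n_zones):
        a_lo, a_hi = i * sector, (i + 1) * sector
        angles = [a_lo + (a_hi - a_lo) * k / arc_steps for k in range(arc_steps + 1)]
        outer = [(r_outer * math.cos(a), r_outer * math.sin(a)) for a in angles]
        inner = [
            (r_inner * math.cos(a), r_inner * math.sin(a)) for a in reversed(angles)
        ]
        poly_arm = Polygon(outer + inner)
        world_pts = [
            g.world_from_arm(Point3D(x, y, 0.0)) for x, y in poly_arm.exterior.coords
        ]
        poly_world = Polygon([(p.x, p.y) for p in world_pts])
        zones[f"Z{i + 1}"] = poly_world
    layout = ZoneLayout(zones=zones)
    # Clip to the marker-bounded rectangle for safety.
    layout.zones = {
        zid: poly.intersection(layout.work_area) for zid, poly in layout.zones.items()
    }
    return layout


def zone_of(point: Iterable[float], layout: ZoneLayout) -> str:
    """Zone id ("Z1".."Zn") containing a table-frame 2-D point, or
    ``"outside"``.  Boundary points go to the lowest-numbered zone."""
    x, y = point
    p = _ShapelyPoint(float(x), float(y))
    if not layout.work_area.covers(p):
        return "outside"
    for zid in sorted(layout.zones):
        if layout.zones[zid].covers(p):
            return zid
    return "outside"
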