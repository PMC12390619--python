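"""Gradient-descent path optimisation for the 3-DoF reach arm.

The planner drives the joint angles from the home pose toward a target
end-effector position by descending the sum-of-squared-errors loss

    E(theta) = sum_{i in x,y,z} (P_i,target - P_i,current)^2   [cm^2]

with analytic partial derivatives of the forward kinematics and a fixed
learning rate shared by all three joints (default 0.001, error
threshold 0.1 cm^2).  Alongside the exact "written" angle sequence, a
quantised "read" sequence models hobby-servo feedback that registers
commands only when they move at least one resolution quantum (default
0.063 rad) away from the current position, producing the characteristic
stepped read-back trace.
"""

from __future__ import annotations

import csv
import io
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kinematics import (
    HOME,
    ArmGeometry,
    JointAngles,
    Point3D,
    UnreachableTargetError,
    forward_kinematics,
    is_reachable,
)

__all__ = [
    "GDConfig",
    "OptimizationTrace",
    "SafeApproachPlan",
    "FaultStatus",
    "sse_loss",
    "loss_gradient",
    "gd_update",
    "plan_reach",
    "simulate_servo_readout",
    "total_positional_error",
    "plan_safe_approach",
    "servo_fault_check",
    "ApproachInfeasibleError",
]


class ApproachInfeasibleError(ValueError):
    """Raised when the hover point of a safe approach is unreachable."""


@dataclass(frozen=True)
class GDConfig:
    """Tunable parameters of the descent planner.

    eta : learning rate (per-iteration step scale), same for all joints.
    sse_threshold : convergence threshold on the loss (cm^2).
    max_iterations : iteration cap; hitting it yields an explicit
        not-converged status, never a silent stop.
    quantum : servo read-back resolution (rad).
    approach_clearance : hover height above the target for the two-phase
        vertical approach (cm).
    """

    eta: float = 0.001
    sse_threshold: float = 0.1
    max_iterations: int = 100_000
    quantum: float = 0.063
    approach_clearance: float = 5.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.sse_threshold <= 0:
            raise ValueError("sse_threshold must be positive")
        if self.quantum <= 0:
            raise ValueError("quantum must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")


def sse_loss(current: Point3D, target: Point3D) -> float:
    """Sum of squared coordinate errors between two EE positions (cm^2)."""
    d = target.as_array() - current.as_array()
    return float(d @ d)


def _jacobian(q: JointAngles, g: ArmGeometry) -> np.ndarray:
    """3x3 Jacobian dP/dtheta of the EE position."""
    c1, s1 = math.cos(q.theta1), math.sin(q.theta1)
    c2, s2 = math.cos(q.theta2), math.sin(q.theta2)
    c23 = math.cos(q.theta2 + q.theta3)
    s23 = math.sin(q.theta2 + q.theta3)
    radial = g.a1 + g.a2 * c2 + g.a3 * c23
    drop = g.a2 * s2 + g.a3 * s23
    return np.array(
        [
            [-radial * s1, -drop * c1, -g.a3 * s23 * c1],
            [radial * c1, -drop * s1, -g.a3 * s23 * s1],
            [0.0, g.a2 * c2 + g.a3 * c23, g.a3 * c23],
        ]
    )


def loss_gradient(q: JointAngles, target: Point3D, g: ArmGeometry) -> np.ndarray:
    """Analytic gradient dE/dtheta of the SSE loss (cm^2/rad).

    With residual r = target - current position, the gradient is
    ``-2 J^T r`` where J is the position Jacobian; it vanishes exactly
    when the EE sits on the target.
    """
    r = target.as_array() - forward_kinematics(q, g).as_array()
    return -2.0 * (_jacobian(q, g).T @ r)


def gd_update(
    q: JointAngles, target: Point3D, g: ArmGeometry, eta: float
) -> JointAngles:
    """One descent step: ``theta_new = theta_old - eta * grad E``."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    return JointAngles.from_array(q.as_array() - eta * loss_gradient(q, target, g))


class _ServoQuantizer:
    """Online model of the quantised servo read-back, one joint each.

    The read value stays put until the written command differs from it
    by at least one quantum, then snaps to the written value.
    """

    def __init__(self, initial: np.ndarray, quantum: float) -> None:
        self.read = np.asarray(initial, dtype=float).copy()
        self.quantum = quantum

    def write(self, written: np.ndarray) -> np.ndarray:
        moved = np.abs(written - self.read) >= self.quantum
        self.read[moved] = written[moved]
        return self.read.copy()


def simulate_servo_readout(written: Sequence, quantum: float) -> np.ndarray:
    """Quantised read-back for a written angle sequence.

    ``written`` is an (n,) sequence for one joint or an (n, k) array for
    k joints (each joint quantised independently).  The first read
    equals the first written value (servo starts aligned).
    """
    w = np.asarray(written, dtype=float)
    if w.ndim == 1:
        return simulate_servo_readout(w[:, None], quantum)[:, 0]
    if w.shape[0] == 0:
        return w.copy()
    quantizer = _ServoQuantizer(w[0], quantum)
    out = np.empty_like(w)
    out[0] = quantizer.read
    for i in range(1, w.shape[0]):
        out[i] = quantizer.write(w[i])
    return out


@dataclass
class OptimizationTrace:
    """Per-iteration record of one reach plan.

    ``written`` holds the exact descent iterates (the "dummy variable"
    the controller keeps updating even below servo resolution);
    ``read`` the quantised servo positions; ``sse`` the loss at each
    written iterate.  Row 0 is the start pose, so ``iterations`` counts
    descent updates actually applied.
    """

    target: Point3D
    written: np.ndarray
    read: np.ndarray
    sse: np.ndarray
    converged: bool
    status: str  # "converged" | "max-iterations" | "halted by override"
    iterations: int

    @property
    def final_written(self) -> JointAngles:
        return JointAngles.from_array(self.written[-1])

    @property
    def final_read(self) -> JointAngles:
        return JointAngles.from_array(self.read[-1])

    @property
    def final_sse(self) -> float:
        return float(self.sse[-1])

    def to_json(self) -> str:
        return json.dumps(
            {
                "target": list(self.target.as_array()),
                "written": self.written.tolist(),
                "read": self.read.tolist(),
                "sse": self.sse.tolist(),
                "converged": self.converged,
                "status": self.status,
                "iterations": self.iterations,
            }
        )

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(
            ["iteration", "w1", "w2", "w3", "r1", "r2", "r3", "sse_cm2"]
        )
        for i in range(self.written.shape[0]):
            writer.writerow(
                [i, *self.written[i], *self.read[i], self.sse[i]]
            )
        return buf.getvalue()


def plan_reach(
    target: Point3D,
    g: ArmGeometry,
    cfg: GDConfig | None = None,
    start: JointAngles = HOME,
    override=None,
) -> OptimizationTrace:
    """Descend the SSE loss from ``start`` until it crosses the threshold.

    Raises :class:`UnreachableTargetError` before iterating if the
    target fails the reachability check.  Joint limits are enforced by
    clamping (with a warning) since the loss itself is unconstrained.
    ``override`` may be an :class:`~neuroreach.pipeline.OverrideLatch`;
    a latched override halts the plan at the next iteration.
    """
    cfg = cfg or GDConfig()
    reach = is_reachable(target, g)
    if not reach:
        raise UnreachableTargetError(f"target not reachable: {reach.reason}")

    tgt = target.as_array()
    q = start.as_array().copy()
    lo = np.array([l for l, _ in g.joint_limits])
    hi = np.array([h for _, h in g.joint_limits])

    quantizer = _ServoQuantizer(q, cfg.quantum)
    written = [q.copy()]
    read = [quantizer.read.copy()]
    warned = False

    def current_sse(angles: np.ndarray) -> float:
        d = tgt - forward_kinematics(JointAngles.from_array(angles), g).as_array()
        return float(d @ d)

    sse = [current_sse(q)]
    status = "max-iterations"
    converged = False
    for _ in range(cfg.max_iterations):
        if override is not None and override.halted:
            status = "halted by override"
            break
        if sse[-1] < cfg.sse_threshold:
            converged = True
            status = "converged"
            break
        grad = loss_gradient(JointAngles.from_array(q), target, g)
        q = q - cfg.eta * grad
        clipped = np.clip(q, lo, hi)
        if not warned and np.any(clipped != q):
            warnings.warn(
                "joint limits reached during descent; angles clamped",
                RuntimeWarning,
                stacklevel=2,
            )
            warned = True
        q = clipped
        written.append(q.copy())
        read.append(quantizer.write(q))
        sse.append(current_sse(q))
    else:
        # Loop exhausted without hitting the threshold.
        if sse[-1] < cfg.sse_threshold:
            converged = True
            status = "converged"
    return OptimizationTrace(
        target=target,
        written=np.asarray(written),
        read=np.asarray(read),
        sse=np.asarray(sse),
        converged=converged,
        status=status,
        iterations=len(written) - 1,
    )


def total_positional_error(
    trace: OptimizationTrace, cfg: GDConfig, g: ArmGeometry
) -> float:
    """Terminal positional error budget (cm^2).

    The convergence threshold bounds how far the *written* solution may
    sit from the target; the servo quantum leaves a further gap between
    the written and read poses.  The total is::

        sse_threshold + || FK(final written) - FK(final read) ||^2
    """
    if trace.written.shape[0] == 0:
        raise ValueError("trace is empty")
    pw = forward_kinematics(trace.final_written, g).as_array()
    pr = forward_kinematics(trace.final_read, g).as_array()
    d = pw - pr
    return cfg.sse_threshold + float(d @ d)


@dataclass
class SafeApproachPlan:
    """Two-phase reach: hover above the target, then descend vertically.

    ``commands`` lists the phase-2 joint commands in actuation order;
    the elbow joint (J3) is always commanded before the shoulder pitch
    (J2) so the EE drops onto the target from above.
    """

    hover_target: Point3D
    phase1: OptimizationTrace
    phase2: OptimizationTrace
    commands: list = field(default_factory=list)

    @property
    def final_sse(self) -> float:
        return self.phase2.final_sse


def plan_safe_approach(
    target: Point3D,
    g: ArmGeometry,
    cfg: GDConfig | None = None,
    start: JointAngles = HOME,
    override=None,
) -> SafeApproachPlan:
    """Plan a reach that stays above the target until the final descent."""
    cfg = cfg or GDConfig()
    hover = Point3D(target.x, target.y, target.z + cfg.approach_clearance)
    for point, label in ((hover, "hover point"), (target, "target")):
        reach = is_reachable(point, g)
        if not reach:
            raise ApproachInfeasibleError(
                f"{label} not reachable: {reach.reason}"
            )
    phase1 = plan_reach(hover, g, cfg, start=start, override=override)
    phase2 = plan_reach(
        target, g, cfg, start=phase1.final_written, override=override
    )
    final = phase2.final_written
    start2 = phase2.written[0]
    commands = []
    # Descent order: J3 before J2 (then J1 if the azimuth still moved).
    for joint, idx in (("J3", 2), ("J2", 1), ("J1", 0)):
        if final.as_array()[idx] != start2[idx]:
            commands.append((joint, float(final.as_array()[idx])))
    return SafeApproachPlan(
        hover_target=hover, phase1=phase1, phase2=phase2, commands=commands
    )


@dataclass(frozen=True)
class FaultStatus:
    ok: bool
    joint: Optional[str] = None

    def __bool__(self) -> bool:
        return self.ok


def servo_fault_check(
    written: JointAngles, read: JointAngles, tol: float = 0.1
) -> FaultStatus:
    """Flag a servo fault when any |written - read| strictly exceeds
    ``tol`` radians (a mismatch of exactly ``tol`` is still ok)."""
    diffs = np.abs(written.as_array() - read.as_array())
    for idx, d in enumerate(diffs):
        if d > tol:
            return FaultStatus(False, f"J{idx + 1}")
    return FaultStatus(True)
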