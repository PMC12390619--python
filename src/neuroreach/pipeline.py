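"""End-to-end trial orchestration, tallies, latency ledger and usability
scoring.

A simulated trial runs the full closed loop: validate the fiducial
markers, fit the pixel->table map, decode the band-power stream into
selection events, align events with the prompt timeline, map the
selected detection to a reach target and plan the arm motion.  Trial
outcomes (TP/FP/FN/TN for clench detection) are tallied into confusion
metrics, per-subsystem latencies are summed into a ledger, and the two
standard usability instruments (the ten-item usability scale and the
six-subscale workload index) are scored from questionnaire responses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from .gd_planner import (
    GDConfig,
    SafeApproachPlan,
    plan_safe_approach,
    servo_fault_check,
)
from .kinematics import ArmGeometry, is_reachable
from .perception import (
    MARKER_INVALID_MESSAGE,
    estimate_planar_map,
    target_world_coordinates,
    validate_markers,
)
from .scdc import ClassificationMetrics, classification_metrics, decode_stream
from .synthetic_data import Scene, SessionTimeline

__all__ = [
    "TrialConfig",
    "TrialLog",
    "LatencyLedger",
    "UsabilityResponses",
    "OverrideLatch",
    "emergency_override",
    "run_trial",
    "tally_confusion",
    "latency_ledger",
    "sus_score",
    "tlx_scaled_average",
]


# ---------------------------------------------------------------------------
# Emergency override
# ---------------------------------------------------------------------------


class OverrideLatch:
    """Latched emergency stop.

    Any trigger halts actuation at the next simulation step and stays
    latched until an explicit :meth:`reset` — resuming without a reset
    keeps the system halted.
    """

    def __init__(self) -> None:
        self._halted = False

    @property
    def halted(self) -> bool:
        return self._halted

    def trigger(self) -> None:
        self._halted = True

    def reset(self) -> None:
        self._halted = False


def emergency_override(latch: OverrideLatch) -> OverrideLatch:
    """Signal the override (any key press in the physical system)."""
    latch.trigger()
    return latch


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------


@dataclass
class TrialConfig:
    session: SessionTimeline
    gd: GDConfig = field(default_factory=GDConfig)
    debounce_k: int = 1
    object_height: float = 0.0
    override: Optional[OverrideLatch] = None
    trial_id: int = 0


@dataclass
class TrialLog:
    """Record of one simulated trial."""

    trial_id: int
    status: str  # "completed" | "aborted" | "servo fault" | "halted by override"
    message: Optional[str]
    detected_objects: List[str]
    true_clench_time: Optional[float]
    decoded_events: List[float]
    selected_object: Optional[str]
    outcome: Optional[str]  # "TP" | "FP" | "FN" | "TN" (None when aborted)
    plan_iterations: Optional[int] = None
    plan_final_sse: Optional[float] = None
    plan_converged: Optional[bool] = None

    def to_json(self) -> str:
        d = dict(self.__dict__)
        return json.dumps(d)


def _classify_outcome(
    session: SessionTimeline, events: Sequence[float]
) -> tuple:
    """Outcome of event/timeline alignment.

    A decoded event inside the target statement's window is a true
    positive (and selects the target); any other decoded event is a
    false positive (selecting whichever statement window it fell in, if
    any); a true clench with no decode is a false negative; a quiet
    trial with no clench is a true negative.  Returns
    (outcome, selected_object_index | None).
    """
    t_lo, t_hi = session.statement_window(session.target_index + 1)
    for t in events:
        if t_lo <= t <= t_hi:
            return "TP", session.target_index
    if events:
        t = events[0]
        for k in range(len(session.objects)):
            lo, hi = session.statement_window(k + 1)
            if lo <= t <= hi:
                return "FP", k
        return "FP", None
    if session.clench_time is not None:
        return "FN", None
    return "TN", None


def run_trial(
    scene: Scene,
    stream,
    model,
    geometry: ArmGeometry,
    cfg: TrialConfig,
) -> TrialLog:
    """Run one closed-loop trial (see module docstring).

    Marker invalidation aborts the trial with the operator-facing
    recalibration message; a read/write mismatch beyond the servo fault
    tolerance, or a latched override, is reported in the status.
    Deterministic given the scene/stream/session seeds.
    """
    session = cfg.session
    names = [d.class_name for d in scene.detections]

    valid = validate_markers(scene.visible_marker_ids)
    if not valid:
        return TrialLog(
            trial_id=cfg.trial_id,
            status="aborted",
            message=valid.message or MARKER_INVALID_MESSAGE,
            detected_objects=names,
            true_clench_time=session.clench_time,
            decoded_events=[],
            selected_object=None,
            outcome=None,
        )

    px, wd, ids = scene.correspondences()
    pmap = estimate_planar_map(px, wd, marker_ids=ids)

    decoded = decode_stream(model, stream, debounce_k=cfg.debounce_k)
    outcome, selected_idx = _classify_outcome(session, decoded.events)

    log = TrialLog(
        trial_id=cfg.trial_id,
        status="completed",
        message=None,
        detected_objects=names,
        true_clench_time=session.clench_time,
        decoded_events=list(decoded.events),
        selected_object=None,
        outcome=outcome,
    )

    if selected_idx is None:
        return log  # no actuation on TN/FN (or unmatched FP)

    selected_name = session.objects[selected_idx]
    log.selected_object = selected_name
    detection = next(
        (d for d in scene.detections if d.class_name == selected_name), None
    )
    if detection is None:
        log.message = f"selected object {selected_name!r} not among detections"
        return log

    target = target_world_coordinates(
        detection, pmap, object_height=cfg.object_height,
        work_area=scene.config.work_area,
    )
    arm_target = geometry.target_from_world(target.point)
    if not is_reachable(arm_target, geometry):
        log.message = "selected target outside the reachable work area"
        return log

    plan: SafeApproachPlan = plan_safe_approach(
        arm_target, geometry, cfg.gd, override=cfg.override
    )
    log.plan_iterations = plan.phase1.iterations + plan.phase2.iterations
    log.plan_final_sse = plan.final_sse
    log.plan_converged = plan.phase1.converged and plan.phase2.converged
    for phase in (plan.phase1, plan.phase2):
        if phase.status == "halted by override":
            log.status = "halted by override"
            return log
        fault = servo_fault_check(phase.final_written, phase.final_read)
        if not fault:
            log.status = "servo fault"
            log.message = f"servo fault at {fault.joint}"
            return log
    return log


def tally_confusion(logs: Sequence[TrialLog]) -> ClassificationMetrics:
    """Sum trial outcomes into confusion counts and derived metrics."""
    if not logs:
        raise ValueError("no trial logs to tally")
    counts = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for log in logs:
        if log.outcome is not None:
            counts[log.outcome] += 1
    return classification_metrics(
        counts["TP"], counts["FP"], counts["FN"], counts["TN"]
    )


# ---------------------------------------------------------------------------
# Latency ledger
# ---------------------------------------------------------------------------


@dataclass
class LatencyLedger:
    """Per-activity latencies (seconds) and their exact sum."""

    components: Dict[str, float]
    total: float

    def render(self) -> str:
        width = max([len("Activity"), *(len(k) for k in self.components)], default=8)
        lines = [f"{'Activity':<{width}}  Latency (s)"]
        for name, value in self.components.items():
            lines.append(f"{name:<{width}}  {value:.6f}")
        lines.append(f"{'Total':<{width}}  {self.total:.6f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({"components": self.components, "total": self.total})


def latency_ledger(components: Mapping[str, float]) -> LatencyLedger:
    """Assemble the ledger; the total is the exact (fsum) component sum."""
    for name, value in components.items():
        if value < 0:
            raise ValueError(f"negative latency for {name!r}")
    return LatencyLedger(
        components=dict(components), total=math.fsum(components.values())
    )


# ---------------------------------------------------------------------------
# Usability scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UsabilityResponses:
    sus: tuple  # ten Likert responses in 1..5
    tlx: tuple  # six scaled subscale scores in [0, 100]

    def __post_init__(self) -> None:
        sus_score(self.sus)
        tlx_scaled_average(self.tlx)


def sus_score(responses: Sequence[int]) -> float:
    """Ten-item usability scale score in [0, 100].

    Odd-numbered items contribute (response - 1), even-numbered items
    (5 - response); the sum is multiplied by 2.5.
    """
    if len(responses) != 10:
        raise ValueError("exactly ten responses required")
    total = 0
    for i, r in enumerate(responses, start=1):
        if not 1 <= r <= 5:
            raise ValueError(f"response {i} out of the 1..5 Likert range")
        total += (r - 1) if i % 2 == 1 else (5 - r)
    return 2.5 * total


def tlx_scaled_average(scaled: Sequence[float]) -> float:
    """Mean of the six scaled workload subscale scores (each 0-100)."""
    if len(scaled) != 6:
        raise ValueError("exactly six subscale scores required")
    for v in scaled:
        if not 0.0 <= v <= 100.0:
            raise ValueError("subscale scores must lie in [0, 100]")
    return math.fsum(scaled) / 6.0
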