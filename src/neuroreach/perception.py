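"""Planar pixel-to-table mapping from fiducial-marker correspondences.

All reach targets sit on one tabletop plane bounded by four square
fiducial markers (50 x 50 mm, IDs 0-3) at the corners of a 600 x 300 mm
work area, so a single 3x3 homography between the image plane and the
table plane replaces full camera pose estimation.  The homography is
fitted by normalised direct linear transform (least squares) to the
marker-corner correspondences; detection bounding boxes are then mapped
through it via their pixel centroids.

Pixel convention: 0-based, origin at the top-left image corner, x to
the right and y down.  Table coordinates are centimetres with the
origin at the centre of marker 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage.transform import ProjectiveTransform

from .kinematics import Point3D

__all__ = [
    "MarkerLayout",
    "PlanarMap",
    "Detection",
    "MarkerValidation",
    "TargetResult",
    "EstimationError",
    "SingularProjectionError",
    "OutOfWorkAreaWarning",
    "MARKER_INVALID_MESSAGE",
    "default_marker_layout",
    "estimate_planar_map",
    "pixel_to_world",
    "world_to_pixel",
    "validate_markers",
    "centroid_of_box",
    "target_world_coordinates",
]

#: Operator-facing message shown when the marker set is unusable.
MARKER_INVALID_MESSAGE = "ArUco not found; please recalibrate"


class EstimationError(ValueError):
    """Raised when the homography cannot be estimated."""


class SingularProjectionError(ValueError):
    """Raised when a point maps to infinity under the homography."""


class OutOfWorkAreaWarning(UserWarning):
    """A mapped target centroid fell outside the work-area rectangle."""


@dataclass
class MarkerLayout:
    """World-plane geometry of the four corner markers.

    ``markers`` maps marker id -> (4, 2) array of the square's corner
    coordinates (cm, z = 0), ordered counter-clockwise starting at the
    corner nearest the work-area origin.  Marker 0 sits at the origin
    corner of the 60 x 30 cm work area.
    """

    markers: "dict[int, np.ndarray]"
    work_area: tuple = (60.0, 30.0)
    marker_size: float = 5.0

    def __post_init__(self) -> None:
        if 0 not in self.markers:
            raise ValueError("base marker (id 0) missing from layout")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker ids must be unique")

    def corners(self, ids: Optional[Iterable[int]] = None) -> tuple:
        """Stacked (n, 2) world corners and matching marker-id list."""
        use = sorted(self.markers) if ids is None else sorted(ids)
        pts = np.vstack([self.markers[i] for i in use])
        return pts, use


def default_marker_layout(
    work_area: tuple = (60.0, 30.0), marker_size: float = 5.0
) -> MarkerLayout:
    """Markers centred on the four work-area corners, id 0 at the origin."""
    w, h = work_area
    centres = {0: (0.0, 0.0), 1: (w, 0.0), 2: (w, h), 3: (0.0, h)}
    half = marker_size / 2.0
    markers = {
        mid: np.array(
            [
                [cx - half, cy - half],
                [cx + half, cy - half],
                [cx + half, cy + half],
                [cx - half, cy + half],
            ]
        )
        for mid, (cx, cy) in centres.items()
    }
    return MarkerLayout(markers=markers, work_area=work_area, marker_size=marker_size)


@dataclass
class PlanarMap:
    """Estimated pixel -> table-plane homography.

    ``matrix`` is scale-normalised (H[2, 2] = 1); ``residual`` is the
    RMS reprojection error of the fitting correspondences in pixels.
    """

    matrix: np.ndarray
    residual: float = 0.0
    marker_ids: tuple = ()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-15:
            raise ValueError("homography must be invertible")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")
        if abs(self.matrix[2, 2]) > 1e-15:
            self.matrix = self.matrix / self.matrix[2, 2]

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.matrix.tolist(),
                "residual_px": self.residual,
                "marker_ids": list(self.marker_ids),
            }
        )


@dataclass(frozen=True)
class Detection:
    """One object-detector output: class name, pixel box, confidence."""

    class_name: str
    box: tuple  # (x_min, y_min, x_max, y_max), 0-based, top-left origin
    confidence: float = 1.0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError("degenerate bounding box: need x_min < x_max and y_min < y_max")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class MarkerValidation:
    ok: bool
    reason: Optional[str] = None
    message: Optional[str] = None

    def __bool__(self) -> bool:
        return self.ok


def validate_markers(detected_ids: Iterable[int]) -> MarkerValidation:
    """Marker-set validity rule: at least three markers visible *and*
    the base marker (id 0) among them."""
    ids = set(detected_ids)
    if 0 not in ids:
        return MarkerValidation(False, "base marker missing", MARKER_INVALID_MESSAGE)
    if len(ids) < 3:
        return MarkerValidation(
            False, "fewer than three markers visible", MARKER_INVALID_MESSAGE
        )
    return MarkerValidation(True)


def estimate_planar_map(
    pixel_points: Sequence, world_points: Sequence, marker_ids: Iterable[int] = ()
) -> PlanarMap:
    """Least-squares homography from >= 4 pixel/world correspondences.

    Uses the normalised direct linear transform; the residual reported
    is the RMS reprojection error back into pixel space.
    """
    px = np.asarray(pixel_points, dtype=float)
    wd = np.asarray(world_points, dtype=float)
    if px.shape != wd.shape or px.ndim != 2 or px.shape[1] != 2:
        raise EstimationError("pixel and world points must both be (n, 2)")
    if px.shape[0] < 4:
        raise EstimationError("at least 4 correspondences required")
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(px, wd)
        ok = bool(tform)
    else:  # older scikit-image
        tform = ProjectiveTransform()
        ok = tform.estimate(px, wd)
    if not ok or not np.all(np.isfinite(tform.params)):
        raise EstimationError("degenerate correspondence configuration")
    H = tform.params
    if abs(np.linalg.det(H)) < 1e-15:
        raise EstimationError("degenerate correspondence configuration")
    back = ProjectiveTransform(matrix=np.linalg.inv(H))(wd)
    residual = float(np.sqrt(np.mean(np.sum((back - px) ** 2, axis=1))))
    return PlanarMap(matrix=H, residual=residual, marker_ids=tuple(marker_ids))


def _apply_homography(H: np.ndarray, p: Sequence) -> np.ndarray:
    v = H @ np.array([float(p[0]), float(p[1]), 1.0])
    if abs(v[2]) < 1e-12 * max(1.0, abs(v[0]), abs(v[1])):
        raise SingularProjectionError("point maps to infinity under the homography")
    return v[:2] / v[2]


def pixel_to_world(pmap: PlanarMap, p: Sequence) -> np.ndarray:
    """Map a pixel point to table-plane coordinates (cm, z = 0)."""
    return _apply_homography(pmap.matrix, p)


def world_to_pixel(pmap: PlanarMap, p: Sequence) -> np.ndarray:
    """Inverse map: table-plane point (cm) to pixel coordinates."""
    return _apply_homography(np.linalg.inv(pmap.matrix), p)


def centroid_of_box(d: Detection) -> tuple:
    """Pixel centroid of a detection's bounding box."""
    x0, y0, x1, y1 = d.box
    return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass(frozen=True)
class TargetResult:
    point: Point3D
    in_work_area: bool


def target_world_coordinates(
    d: Detection,
    pmap: PlanarMap,
    object_height: float = 0.0,
    work_area: tuple = (60.0, 30.0),
) -> TargetResult:
    """Reach-target coordinates for a detection.

    The box centroid is mapped through the homography onto the table
    plane; z is set to the configured object height (default 0, i.e.
    the tabletop).  A centroid landing outside the work-area rectangle
    raises :class:`OutOfWorkAreaWarning` but the coordinates are still
    returned.
    """
    cx, cy = centroid_of_box(d)
    wx, wy = pixel_to_world(pmap, (cx, cy))
    w, h = work_area
    inside = (0.0 - 1e-9) <= wx <= w + 1e-9 and (0.0 - 1e-9) <= wy <= h + 1e-9
    if not inside:
        warnings.warn(
            f"target centroid ({wx:.2f}, {wy:.2f}) cm outside the work area",
            OutOfWorkAreaWarning,
            stacklevel=2,
        )
    return TargetResult(Point3D(float(wx), float(wy), float(object_height)), inside)
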