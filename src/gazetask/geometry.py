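"""Scene geometry and gaze cueing in normalized viewport coordinates.

The scene is described in viewport-width units: x runs from 0 (left) to 1
(right), y increases upward, and the target lands on a horizontal ground
line at ``ground_y``.  An animated agent looks at the target; its pupils sit
on a circle of radius ``pupil_offset`` around each eye center, displaced
toward the target.  The ideal observer inverts this cue: extend the
eye-to-pupil ray until it meets the ground line and read off x.

All default proportions (eye positions, pupil offset, target width) are
package conventions chosen to resemble a desk-scale scene; they are not
measurements of any particular stimulus set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GeometryError",
    "Point2D",
    "SceneLayout",
    "GazePose",
    "pose_for_target",
    "infer_ground_x",
    "flight_duration",
]


class GeometryError(ValueError):
    """Degenerate scene geometry (coincident points, non-intersecting rays)."""


@dataclass(frozen=True)
class Point2D:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite point ({self.x}, {self.y})")


def _default_box_edges(n_boxes: int) -> tuple[float, ...]:
    return tuple(i / n_boxes for i in range(n_boxes + 1))


@dataclass(frozen=True)
class SceneLayout:
    """Normalized scene description shared by both task versions.

    Parameters
    ----------
    eye_centers : two eye centers, strictly above the ground line.
    pupil_offset : radius of the circle the pupil center moves on.
    ground_y : y of the line on which targets land.
    viewport_aspect : height/width ratio of the viewport (metadata only).
    target_width : width of the target; the unit of click imprecision.
    n_bins : number of equal-width target bins (continuous "hedge" version).
    n_boxes : number of hiding boxes, 1..8 (discrete "box" version).
    box_edges : increasing x-partition of [0, 1] into ``n_boxes`` boxes.
    """

    eye_centers: tuple[Point2D, Point2D] = (Point2D(0.46, 0.70), Point2D(0.54, 0.70))
    pupil_offset: float = 0.02
    ground_y: float = 0.15
    viewport_aspect: float = 0.75
    target_width: float = 0.05
    n_bins: int = 10
    n_boxes: int = 5
    box_edges: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pupil_offset <= 0:
            raise GeometryError("pupil_offset must be positive")
        if self.target_width <= 0:
            raise GeometryError("target_width must be positive")
        if not 1 <= self.n_boxes <= 8:
            raise GeometryError("n_boxes must be between 1 and 8")
        if self.n_bins < 1:
            raise GeometryError("n_bins must be >= 1")
        for eye in self.eye_centers:
            if eye.y <= self.ground_y:
                raise GeometryError("eye centers must lie strictly above the ground line")
        if self.box_edges is None:
            object.__setattr__(self, "box_edges", _default_box_edges(self.n_boxes))
        edges = self.box_edges
        if len(edges) != self.n_boxes + 1:
            raise GeometryError("box_edges must have n_boxes + 1 entries")
        if abs(edges[0]) > 1e-12 or abs(edges[-1] - 1.0) > 1e-12:
            raise GeometryError("box_edges must span [0, 1]")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise GeometryError("box_edges must be strictly increasing")

    def bin_interval(self, bin_index: int) -> tuple[float, float]:
        """Half-open x-interval [lo, hi) of a 0-based bin."""
        if not 0 <= bin_index < self.n_bins:
            raise GeometryError(f"bin {bin_index} out of range for {self.n_bins} bins")
        return bin_index / self.n_bins, (bin_index + 1) / self.n_bins

    def box_interval(self, box_index: int) -> tuple[float, float]:
        if not 0 <= box_index < self.n_boxes:
            raise GeometryError(f"box {box_index} out of range for {self.n_boxes} boxes")
        return self.box_edges[box_index], self.box_edges[box_index + 1]

    def box_for_x(self, x: float) -> int:
        """0-based box containing x; x on an interior edge belongs to the right box."""
        if not 0.0 <= x <= 1.0:
            raise GeometryError(f"x={x} outside the viewport")
        for i in range(self.n_boxes):
            if x < self.box_edges[i + 1]:
                return i
        return self.n_boxes - 1


@dataclass(frozen=True)
class GazePose:
    """Pupil centers of both eyes for one fixation."""

    pupil_centers: tuple[Point2D, Point2D]


def pose_for_target(layout: SceneLayout, target: Point2D) -> GazePose:
    """Place both pupils so that each lies on the eye-to-target line.

    Each pupil center is ``eye + pupil_offset * unit(target - eye)``, i.e.
    eye center, pupil center and target are collinear and the pupil stays on
    the circle of radius ``pupil_offset``.
    """
    pupils = []
    for eye in layout.eye_centers:
        dx, dy = target.x - eye.x, target.y - eye.y
        norm = math.hypot(dx, dy)
        if norm == 0.0:
            raise GeometryError("target coincides with an eye center")
        pupils.append(
            Point2D(eye.x + layout.pupil_offset * dx / norm, eye.y + layout.pupil_offset * dy / norm)
        )
    return GazePose(pupil_centers=(pupils[0], pupils[1]))


def infer_ground_x(layout: SceneLayout, pose: GazePose) -> float:
    """Ideal-observer inversion: intersect each gaze ray with the ground line.

    For each eye, extend the ray from eye center through pupil center until
    it reaches ``y = ground_y`` and take the x-coordinate; the estimate is
    the mean of the two per-eye intersections.  Rays parallel to the ground
    or pointing away from it raise :class:`GeometryError`.
    """
    xs = []
    for eye, pupil in zip(layout.eye_centers, pose.pupil_centers):
        dx, dy = pupil.x - eye.x, pupil.y - eye.y
        if dy >= 0.0:
            raise GeometryError("gaze ray does not point downward toward the ground line")
        t = (layout.ground_y - eye.y) / dy
        xs.append(eye.x + t * dx)
    return sum(xs) / len(xs)


def flight_duration(start: Point2D, end: Point2D, speed: float) -> float:
    """Travel time of the target at constant speed (Euclidean distance / speed)."""
    if speed <= 0:
        raise GeometryError("speed must be positive")
    return math.hypot(end.x - start.x, end.y - start.y) / speed
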