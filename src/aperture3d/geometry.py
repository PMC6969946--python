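"""Binocular viewing geometry for oriented lines moving in depth.

A line stimulus seen through a circular aperture constrains its own 3D
velocity only up to a line in space: each eye measures the image-motion
gradient (the velocity component perpendicular to the line's image), and
inverse projection of that 2D constraint through the eye's nodal point
yields a *constraint plane*.  The two monocular planes intersect in a 3D
line — the intersection of constraint planes (ICP) — which is the binocular
velocity constraint this module computes.

Coordinate conventions
----------------------
Right-handed world frame: x rightward, y upward, z increasing away from the
observer.  The fixation point ``F`` is the world origin and lies on the
screen plane z = 0.  The eyes sit at z = -D, where D is the viewing
distance; the cyclopean point is the midpoint between the two nodal points.
Internal units are cm and cm/s; degrees of visual angle appear only at the
interface and are converted with the exact ``tan`` relation at distance D.

Velocities and unit-time displacements are used interchangeably: a
constraint plane is built from the image line displaced by its gradient
over 1 s, so points on the ICP are 3D velocities in cm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Eye = Literal["left", "right"]

_PLANE_TOL = 1e-9


class DegenerateProjectionError(ValueError):
    """Projection ray is (numerically) parallel to the screen plane."""


class DegenerateICPError(ValueError):
    """Constraint planes are parallel: the stimulus is unresolvable."""


class DegenerateCAError(ValueError):
    """Cyclopean ray is parallel to the ICP."""


def deg_to_cm(deg: float, distance_cm: float) -> float:
    """Visual angle (deg) to cm on the screen plane at ``distance_cm``."""
    return distance_cm * math.tan(math.radians(deg))


def cm_to_deg(cm: float, distance_cm: float) -> float:
    """Inverse of :func:`deg_to_cm`."""
    return math.degrees(math.atan2(cm, distance_cm))


def normalize_theta(theta_deg: float) -> float:
    """Reduce a line orientation (deg from vertical) to (-90, 90]."""
    t = (theta_deg + 90.0) % 180.0 - 90.0
    return 90.0 if t == -90.0 else t


@dataclass(frozen=True)
class ViewingGeometry:
    """Observer/screen layout: fixation at the origin, eyes at z = -D."""

    distance_cm: float = 55.0
    ipd_cm: float = 6.5

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise ValueError("viewing distance must be positive")
        if self.ipd_cm <= 0:
            raise ValueError("interpupillary distance must be positive")

    @property
    def left_eye(self) -> np.ndarray:
        return np.array([-self.ipd_cm / 2.0, 0.0, -self.distance_cm])

    @property
    def right_eye(self) -> np.ndarray:
        return np.array([self.ipd_cm / 2.0, 0.0, -self.distance_cm])

    @property
    def cyclopean(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.distance_cm])

    def nodal_point(self, eye: Eye) -> np.ndarray:
        return self.left_eye if eye == "left" else self.right_eye


@dataclass(frozen=True)
class StimulusCondition:
    """One oriented-line condition of the motion-direction matching task.

    ``tilt_deg`` is the mean image-line orientation from vertical;
    ``orientation_disparity_deg`` is the signed left-minus-right difference
    between the two eyes' image-line orientations, which renders the fused
    line slanted in depth.  The line images translate along the axis
    perpendicular to the mean orientation with speeds
    ``base_speed ± iovd_sign * iovd_magnitude / 2`` (left/right eye), so
    the interocular velocity difference (IOVD) is fixed in magnitude and
    its sign selects approaching (+) versus receding (-) motion.
    """

    tilt_deg: float = 0.0
    orientation_disparity_deg: float = 0.0
    iovd_sign: int = 1
    base_speed_deg: float = 3.0
    iovd_magnitude_deg: float = 0.46
    aperture_radius_deg: float = 2.41
    experiment: int = 1

    def __post_init__(self) -> None:
        if self.iovd_sign not in (-1, 1):
            raise ValueError("iovd_sign must be +1 or -1")
        if min(self.left_speed_deg, self.right_speed_deg) <= 0:
            raise ValueError("left/right image speeds must both be positive")

    @property
    def left_speed_deg(self) -> float:
        return self.base_speed_deg + self.iovd_sign * self.iovd_magnitude_deg / 2.0

    @property
    def right_speed_deg(self) -> float:
        return self.base_speed_deg - self.iovd_sign * self.iovd_magnitude_deg / 2.0

    @property
    def theta_left_deg(self) -> float:
        return normalize_theta(self.tilt_deg + self.orientation_disparity_deg / 2.0)

    @property
    def theta_right_deg(self) -> float:
        return normalize_theta(self.tilt_deg - self.orientation_disparity_deg / 2.0)

    def key(self) -> tuple:
        return (
            self.experiment,
            self.tilt_deg,
            self.orientation_disparity_deg,
            self.iovd_sign,
        )

    def mirrored(self) -> "StimulusCondition":
        """The x-reflected condition (tilt -> -tilt, IOVD sign flipped).

        Reflection across the y-z plane swaps the eyes, so the left/right
        speed assignment flips (iovd_sign -> -iovd_sign) while the
        orientation disparity is preserved.
        """
        return replace(
            self,
            tilt_deg=(-self.tilt_deg) % 180.0,
            iovd_sign=-self.iovd_sign,
        )


@dataclass(frozen=True)
class Line3D:
    """A 3D line given by a point and a direction (need not be unit)."""

    point: np.ndarray
    direction: np.ndarray


@dataclass(frozen=True)
class ImageLine:
    """A line image on the screen plane of one eye.

    ``theta_deg`` is measured from vertical in the screen plane, in
    (-90, 90]; ``anchor_cm`` is any point on the line (2D screen cm).
    """

    eye: Eye
    theta_deg: float
    anchor_cm: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def direction(self) -> np.ndarray:
        t = math.radians(self.theta_deg)
        return np.array([math.sin(t), math.cos(t)])


@dataclass(frozen=True)
class ImageGradient:
    """Image-motion gradient: velocity component perpendicular to the line."""

    eye: Eye
    vector_cm_s: np.ndarray
    ambiguous: bool = False


@dataclass(frozen=True)
class ConstraintPlane:
    """Plane {x : n.x = c} through one eye's nodal point."""

    normal: np.ndarray
    offset: float
    eye: Eye

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.normal - self.offset


@dataclass(frozen=True)
class ICPLine:
    """Intersection of the two constraint planes: p0 + t d, |d| = 1.

    The anchor ``point`` is the point on the line closest to the origin
    (the motion start point), so the vector-normal estimate is immediate.
    """

    point: np.ndarray
    direction: np.ndarray


@dataclass(frozen=True)
class SphericalDirection:
    """Motion direction as longitude/latitude about the start point.

    Longitude is the depth azimuth measured from the horizontal x-axis in
    the x-z plane, positive for motion toward the observer; latitude is the
    elevation from the horizontal x-z plane, positive upward.
    """

    longitude_deg: float
    latitude_deg: float


# ---------------------------------------------------------------------------
# projection


def _project_point(p: np.ndarray, geometry: ViewingGeometry, eye: Eye) -> np.ndarray:
    nodal = geometry.nodal_point(eye)
    denom = p[2] - nodal[2]  # = p_z + D
    if abs(denom) < 1e-12 * max(1.0, geometry.distance_cm):
        raise DegenerateProjectionError("projection ray parallel to screen plane")
    t = -nodal[2] / denom
    proj = nodal + t * (p - nodal)
    return proj[:2]


def project_to_eye(obj, geometry: ViewingGeometry, eye: Eye):
    """Central projection through the eye's nodal point onto z = 0.

    Accepts a 3D point (returns a 2D screen point) or a :class:`Line3D`
    (returns an :class:`ImageLine`).  A ray parallel to the screen plane
    raises :class:`DegenerateProjectionError`.
    """
    if isinstance(obj, Line3D):
        p1 = np.asarray(obj.point, dtype=float)
        d = np.asarray(obj.direction, dtype=float)
        if np.linalg.norm(d) < 1e-12:
            raise ValueError("line direction must be nonzero")
        nodal = geometry.nodal_point(eye)
        if np.linalg.norm(np.cross(p1 - nodal, d)) < 1e-12:
            raise DegenerateProjectionError("line passes through the nodal point")
        q1 = _project_point(p1, geometry, eye)
        # choose a second sample point whose ray is not parallel to the screen
        step = 1.0
        p2 = p1 + step * d
        if abs(p2[2] - nodal[2]) < 1e-9:
            p2 = p1 - step * d
        q2 = _project_point(p2, geometry, eye)
        img_dir = q2 - q1
        if np.linalg.norm(img_dir) < 1e-12:
            raise DegenerateProjectionError("line projects to a point")
        theta = normalize_theta(math.degrees(math.atan2(img_dir[0], img_dir[1])))
        return ImageLine(eye=eye, theta_deg=theta, anchor_cm=q1)
    return _project_point(np.asarray(obj, dtype=float), geometry, eye)


def image_gradient(image_line: ImageLine, carrier_cm_s: np.ndarray) -> ImageGradient:
    """Component of the carrier velocity perpendicular to the image line.

    Pure tangential motion (carrier parallel to the line) yields a zero
    gradient flagged ``ambiguous``.
    """
    carrier = np.asarray(carrier_cm_s, dtype=float)
    ldir = image_line.direction
    g = carrier - (carrier @ ldir) * ldir
    speed = np.linalg.norm(carrier)
    ambiguous = bool(np.linalg.norm(g) < 1e-12 * max(1.0, speed))
    if ambiguous:
        g = np.zeros(2)
    return ImageGradient(eye=image_line.eye, vector_cm_s=g, ambiguous=ambiguous)


def constraint_plane(
    image_line: ImageLine, gradient: ImageGradient, geometry: ViewingGeometry
) -> ConstraintPlane:
    """Inverse-project the displaced image line through the nodal point.

    The plane contains the eye's nodal point and the image line displaced
    by the gradient over unit time; it holds every 3D position consistent
    with the eye's measurement.
    """
    if gradient.eye != image_line.eye:
        raise ValueError("gradient and image line must come from the same eye")
    nodal = geometry.nodal_point(image_line.eye)
    a = image_line.anchor_cm + gradient.vector_cm_s
    q1 = np.array([a[0], a[1], 0.0])
    ld = image_line.direction
    q2 = q1 + np.array([ld[0], ld[1], 0.0])
    n = np.cross(q1 - nodal, q2 - nodal)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("degenerate image line: zero-length plane normal")
    n = n / norm
    return ConstraintPlane(normal=n, offset=float(n @ nodal), eye=image_line.eye)


def intersect_planes(p_left: ConstraintPlane, p_right: ConstraintPlane) -> ICPLine:
    """Intersection of the two constraint planes (the ICP).

    Direction is the normalized cross product of the plane normals; the
    anchor is the point on the line closest to the origin.  Parallel planes
    raise :class:`DegenerateICPError`.
    """
    n1, n2 = p_left.normal, p_right.normal
    cross = np.cross(n1, n2)
    norm = np.linalg.norm(cross)
    if norm < _PLANE_TOL:
        raise DegenerateICPError("parallel planes")
    d = cross / norm
    N = np.vstack([n1, n2])
    c = np.array([p_left.offset, p_right.offset])
    # minimum-norm point satisfying both plane equations; lies in the row
    # space of N, hence perpendicular to d
    p0 = N.T @ np.linalg.solve(N @ N.T, c)
    return ICPLine(point=p0, direction=d)


# ---------------------------------------------------------------------------
# spherical direction angles


def to_spherical(v: np.ndarray) -> SphericalDirection:
    """Longitude/latitude of a 3D velocity about the start point.

    Longitude alpha = atan2(|v_z|, |v_x|) * sign(-v_z): approaching motion
    (v_z < 0, toward the observer) gets positive longitude regardless of
    its leftward/rightward component.  Latitude beta is the elevation from
    the x-z plane, positive upward.
    """
    v = np.asarray(v, dtype=float)
    if np.linalg.norm(v) < 1e-15:
        raise ValueError("zero vector has no direction")
    vx, vy, vz = v
    alpha = math.degrees(math.atan2(abs(vz), abs(vx)))
    if vz > 0:
        alpha = -alpha
    beta = math.degrees(math.atan2(vy, math.hypot(vx, vz)))
    return SphericalDirection(longitude_deg=alpha, latitude_deg=beta)


def from_spherical(longitude_deg: float, latitude_deg: float, r: float = 1.0) -> np.ndarray:
    """A 3D vector with the given direction angles (leftward representative).

    ``to_spherical`` folds the left/right sign of v_x, so the returned
    vector is the v_x <= 0 member of the direction class; the round trip
    ``to_spherical(from_spherical(a, b))`` preserves (a, b).
    """
    a = math.radians(longitude_deg)
    b = math.radians(latitude_deg)
    return np.array(
        [-r * math.cos(b) * math.cos(a), r * math.sin(b), -r * math.cos(b) * math.sin(a)]
    )


# ---------------------------------------------------------------------------
# stimulus -> constraint chain


def motion_axis(tilt_deg: float) -> np.ndarray:
    """Unit screen axis along which the line images translate.

    Perpendicular to the mean line orientation: horizontal for a vertical
    line (tilt 0), oblique for tilted lines.
    """
    t = math.radians(tilt_deg)
    return np.array([math.cos(t), -math.sin(t)])


def stimulus_image_lines(
    cond: StimulusCondition, geometry: ViewingGeometry
) -> tuple[ImageLine, ImageLine]:
    """The two eyes' image lines at motion onset (anchored at fixation)."""
    return (
        ImageLine(eye="left", theta_deg=cond.theta_left_deg),
        ImageLine(eye="right", theta_deg=cond.theta_right_deg),
    )


def stimulus_gradients(
    cond: StimulusCondition, geometry: ViewingGeometry
) -> tuple[ImageGradient, ImageGradient]:
    """Image-motion gradients of both eyes for a condition, in cm/s."""
    line_l, line_r = stimulus_image_lines(cond, geometry)
    axis = motion_axis(cond.tilt_deg)
    D = geometry.distance_cm
    carrier_l = deg_to_cm(cond.left_speed_deg, D) * axis
    carrier_r = deg_to_cm(cond.right_speed_deg, D) * axis
    return image_gradient(line_l, carrier_l), image_gradient(line_r, carrier_r)


def condition_icp(cond: StimulusCondition, geometry: ViewingGeometry) -> ICPLine:
    """Full constraint chain: image lines -> gradients -> planes -> ICP."""
    line_l, line_r = stimulus_image_lines(cond, geometry)
    grad_l, grad_r = stimulus_gradients(cond, geometry)
    plane_l = constraint_plane(line_l, grad_l, geometry)
    plane_r = constraint_plane(line_r, grad_r, geometry)
    return intersect_planes(plane_l, plane_r)


def triangulate_displaced_line(
    cond: StimulusCondition, geometry: ViewingGeometry
) -> np.ndarray:
    """Ray-tracing oracle for the zero-orientation-disparity case.

    For a vertical line (equal orientations in the two eyes) the displaced
    left/right image lines correspond in depth, and triangulating the
    displaced horizontal positions through the two nodal points gives the
    unique new 3D position of the line at y = 0.
    """
    grad_l, grad_r = stimulus_gradients(cond, geometry)
    xl = grad_l.vector_cm_s[0]
    xr = grad_r.vector_cm_s[0]
    le, re = geometry.left_eye, geometry.right_eye
    # intersect rays LE->(xl, 0) and RE->(xr, 0) in the x-z plane
    d1 = np.array([xl, 0.0, 0.0]) - le
    d2 = np.array([xr, 0.0, 0.0]) - re
    A = np.array([[d1[0], -d2[0]], [d1[2], -d2[2]]])
    b = (re - le)[[0, 2]]
    t = np.linalg.solve(A, b)
    return le + t[0] * d1
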