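"""Geometric primitives for implant wear metrology.

Least-squares sphere and plane fits with residual-based outlier
elimination, and rigid coordinate frames anchored on the acetabular cup.
All lengths are in millimetres, all angles in degrees, and coordinate
systems are right-handed.

The fitting strategy mirrors standard dimensional-metrology practice:
a closed-form algebraic estimate initialises a geometric (orthogonal
distance) least-squares refinement, and points lying more than a
threshold distance (default 0.5 mm) from the fitted surface — typically
metal artifacts in CT-derived point sets — are eliminated and the fit
repeated until it reaches a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PointCloud",
    "SphereFit",
    "PlaneFit",
    "CupFrame",
    "RigidTransform",
    "FitDegeneracyError",
    "FitConvergenceError",
    "DegenerateAzimuthError",
    "fit_sphere",
    "fit_plane",
    "filter_to_surface",
    "build_cup_frame",
    "frame_transform",
]

#: Surface labels recognised throughout the pipeline.
VALID_LABELS = frozenset({"cup_outer", "cup_inner", "head", "plane1", "plane2"})

#: Default residual threshold for artifact elimination (mm).
DEFAULT_FILTER_THRESHOLD = 0.5

#: Parameter-update convergence tolerance for geometric fits (mm).
FIT_TOL = 1e-12

#: Orthonormality / determinant tolerance for frames and rotations.
ORTHO_TOL = 1e-9


class FitDegeneracyError(ValueError):
    """Raised when a point set cannot determine the requested primitive."""


class FitConvergenceError(RuntimeError):
    """Raised when the eliminate-and-refit loop fails to reach a fixed point."""


class DegenerateAzimuthError(ValueError):
    """Raised when no in-plane reference direction can be constructed."""


@dataclass(frozen=True)
class PointCloud:
    """Labelled 3D point set (mm) for one surface of one scan.

    Parameters
    ----------
    points
        ``(n, 3)`` array of coordinates in mm. Row order is meaningful
        and preserved by all operations.
    label
        Surface label, one of ``cup_outer``, ``cup_inner``, ``head``,
        ``plane1``, ``plane2``.
    scan_id
        Identifier of the scan the points belong to (e.g. ``"pre"``).
    """

    points: np.ndarray
    label: str
    scan_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("a PointCloud needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"unknown surface label {self.label!r}; expected one of "
                f"{sorted(VALID_LABELS)}"
            )
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def transformed(self, transform: "RigidTransform") -> "PointCloud":
        """Return a copy with the rigid transform applied to every point."""
        return PointCloud(transform.apply(self.points), self.label, self.scan_id)

    def subset(self, mask: np.ndarray) -> "PointCloud":
        pts = self.points[np.asarray(mask)]
        if pts.shape[0] == 0:
            # dataclass invariant requires >= 1 point; represent emptiness
            # with an explicitly empty array bypassing validation
            empty = object.__new__(PointCloud)
            object.__setattr__(empty, "points", pts.reshape(0, 3))
            object.__setattr__(empty, "label", self.label)
            object.__setattr__(empty, "scan_id", self.scan_id)
            return empty
        return PointCloud(pts, self.label, self.scan_id)


@dataclass(frozen=True)
class SphereFit:
    """Sphere fitted by orthogonal-distance least squares.

    ``rms_residual`` is over retained points; ``n_used + n_rejected``
    equals the size of the input cloud.
    """

    center: np.ndarray
    radius: float
    rms_residual: float
    n_used: int
    n_rejected: int

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def residuals(self, points: np.ndarray) -> np.ndarray:
        """Unsigned orthogonal distances of ``points`` from the sphere surface."""
        return np.abs(
            np.linalg.norm(np.asarray(points, float) - self.center, axis=1)
            - self.radius
        )


@dataclass(frozen=True)
class PlaneFit:
    """Plane fitted by total least squares.

    The plane is ``{p : normal . p = offset}`` with ``|normal| = 1``;
    ``offset`` is the signed distance of the plane from the origin along
    the normal. ``centroid`` (mean of retained points) is kept as a
    diagnostic and as the anchor for frame construction.
    """

    normal: np.ndarray
    offset: float
    rms_residual: float
    n_used: int
    n_rejected: int
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def residuals(self, points: np.ndarray) -> np.ndarray:
        """Unsigned orthogonal distances of ``points`` from the plane."""
        return np.abs(np.asarray(points, float) @ self.normal - self.offset)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.normal - self.offset


@dataclass(frozen=True)
class CupFrame:
    """Orthonormal, right-handed local coordinate system anchored on the cup.

    The origin sits at the cup-sphere centre; ``z_axis`` points along
    the mean normal of the two opening faces, away from the cup dome
    (i.e. out of the opening); ``x_axis`` lies in the opening plane along
    the intersection line of the two faces.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        R = self.rotation
        if np.max(np.abs(R.T @ R - np.eye(3))) > ORTHO_TOL:
            raise ValueError("frame axes are not orthonormal")
        if np.max(np.abs(np.cross(self.x_axis, self.y_axis) - self.z_axis)) > ORTHO_TOL:
            raise ValueError("frame is not right-handed (x cross y != z)")

    @property
    def rotation(self) -> np.ndarray:
        """World-from-local rotation; columns are the frame axes."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express world points in frame coordinates."""
        p = np.asarray(points, float)
        return (p - self.origin) @ self.rotation

    def from_local(self, points: np.ndarray) -> np.ndarray:
        """Map frame coordinates back to world coordinates."""
        return np.asarray(points, float) @ self.rotation.T + self.origin


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float).reshape(3)
        if np.max(np.abs(R.T @ R - np.eye(3))) > ORTHO_TOL:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > ORTHO_TOL:
            raise ValueError("rotation determinant must be +1 (proper rotation)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# ---------------------------------------------------------------------------
# filtering


def filter_to_surface(
    cloud: PointCloud,
    residual_fn: Callable[[np.ndarray], np.ndarray],
    threshold: float,
) -> tuple[PointCloud, PointCloud]:
    """Partition a cloud by distance from a reference surface.

    A point is eliminated only when its residual is *strictly greater*
    than ``threshold``; a residual exactly at the threshold is retained.
    Row order is preserved in both outputs and
    ``len(retained) + len(rejected) == len(cloud)``.
    """
    if threshold <= 0:
        raise ValueError("filter threshold must be positive")
    res = np.asarray(residual_fn(cloud.points), dtype=float)
    if res.shape != (len(cloud),) or np.any(res < 0):
        raise ValueError("residual_fn must return one nonnegative distance per point")
    keep = res <= threshold
    return cloud.subset(keep), cloud.subset(~keep)


# ---------------------------------------------------------------------------
# sphere fitting


def _algebraic_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Closed-form linearised sphere fit (Coope's method).

    Solves ``|p|^2 = 2 c . p + (r^2 - |c|^2)`` in the least-squares
    sense. Exact on noise-free data; used to initialise the geometric fit
    and, in tests, as an independent cross-check.
    """
    A = np.hstack([2.0 * points, np.ones((points.shape[0], 1))])
    b = np.einsum("ij,ij->i", points, points)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise FitDegeneracyError(
            "sphere fit is degenerate: points are coplanar or collinear"
        )
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise FitDegeneracyError("sphere fit is degenerate: nonpositive radius")
    return center, float(np.sqrt(r2))


def _geometric_sphere(points: np.ndarray, c0: np.ndarray, r0: float) -> tuple[np.ndarray, float]:
    """Orthogonal-distance refinement: minimise sum (|p - c| - r)^2."""

    def fun(x: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points - x[:3], axis=1)
        return d - x[3]

    def jac(x: np.ndarray) -> np.ndarray:
        diff = points - x[:3]
        d = np.linalg.norm(diff, axis=1)
        J = np.empty((points.shape[0], 4))
        J[:, :3] = -diff / d[:, None]
        J[:, 3] = -1.0
        return J

    sol = least_squares(
        fun, np.append(c0, r0), jac=jac, method="lm",
        xtol=FIT_TOL, ftol=FIT_TOL, gtol=FIT_TOL, max_nfev=200,
    )
    return sol.x[:3], float(sol.x[3])


def fit_sphere(
    cloud: PointCloud,
    filter_threshold: float = DEFAULT_FILTER_THRESHOLD,
    max_iterations: int = 10,
) -> SphereFit:
    """Fit a sphere with iterative artifact elimination.

    The sphere minimising the summed squared orthogonal residuals
    ``(|p - c| - r)^2`` is fitted to the cloud; points lying strictly
    more than ``filter_threshold`` mm from the fitted surface are
    eliminated and the fit repeated, until no further point is removed.
    ``max_iterations = 1`` gives the single elimination pass.

    Raises
    ------
    FitDegeneracyError
        Fewer than 4 usable points, or coplanar/collinear points.
    FitConvergenceError
        Elimination has not reached a fixed point after ``max_iterations``.
    """
    if filter_threshold <= 0:
        raise ValueError("filter threshold must be positive")
    pts = cloud.points
    n_input = pts.shape[0]
    for iteration in range(1, max_iterations + 1):
        if pts.shape[0] < 4:
            raise FitDegeneracyError(
                f"sphere fit needs >= 4 points, {pts.shape[0]} remain after filtering"
            )
        c0, r0 = _algebraic_sphere(pts)
        center, radius = _geometric_sphere(pts, c0, r0)
        res = np.abs(np.linalg.norm(pts - center, axis=1) - radius)
        keep = res <= filter_threshold
        if keep.all():
            return SphereFit(
                center=center,
                radius=radius,
                rms_residual=float(np.sqrt(np.mean(res**2))) if res.size else 0.0,
                n_used=int(pts.shape[0]),
                n_rejected=int(n_input - pts.shape[0]),
            )
        pts = pts[keep]
    raise FitConvergenceError(
        f"sphere elimination loop did not converge in {max_iterations} iterations"
    )


# ---------------------------------------------------------------------------
# plane fitting


def _tls_plane(points: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Total-least-squares plane through a point set.

    Returns (unit normal, offset, centroid). The normal is the singular
    vector of the centred points with the smallest singular value.
    """
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if points.shape[0] < 3 or s.size < 3 or (s.size >= 2 and s[1] <= 1e-12 * max(1.0, s[0])):
        raise FitDegeneracyError("plane fit is degenerate: points are collinear")
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    return normal, float(normal @ centroid), centroid


def fit_plane(
    cloud: PointCloud,
    filter_threshold: float = DEFAULT_FILTER_THRESHOLD,
    max_iterations: int = 10,
    positive_side: np.ndarray | None = None,
) -> PlaneFit:
    """Fit a plane by total least squares with iterative artifact elimination.

    Same eliminate-and-refit loop as :func:`fit_sphere`, with residuals
    measured orthogonally to the plane. When ``positive_side`` is given,
    the normal is oriented so that this reference point has nonnegative
    signed distance.
    """
    if filter_threshold <= 0:
        raise ValueError("filter threshold must be positive")
    pts = cloud.points
    n_input = pts.shape[0]
    for iteration in range(1, max_iterations + 1):
        if pts.shape[0] < 3:
            raise FitDegeneracyError(
                f"plane fit needs >= 3 points, {pts.shape[0]} remain after filtering"
            )
        normal, offset, centroid = _tls_plane(pts)
        res = np.abs(pts @ normal - offset)
        keep = res <= filter_threshold
        if keep.all():
            if positive_side is not None:
                side = float(np.asarray(positive_side, float) @ normal - offset)
                if side < 0:
                    normal, offset = -normal, -offset
            return PlaneFit(
                normal=normal,
                offset=offset,
                rms_residual=float(np.sqrt(np.mean(res**2))) if res.size else 0.0,
                n_used=int(pts.shape[0]),
                n_rejected=int(n_input - pts.shape[0]),
                centroid=centroid,
            )
        pts = pts[keep]
    raise FitConvergenceError(
        f"plane elimination loop did not converge in {max_iterations} iterations"
    )


# ---------------------------------------------------------------------------
# cup frame construction


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


#: Two opening-face normals closer than this angle (degrees) are treated
#: as parallel and the azimuth falls back to a fixed world direction.
PARALLEL_PLANES_DEG = 1.0


def build_cup_frame(
    cup_sphere: SphereFit,
    plane1: PlaneFit,
    plane2: PlaneFit,
    opening_reference: np.ndarray | None = None,
    allow_azimuth_fallback: bool = True,
) -> CupFrame:
    """Construct the cup-anchored coordinate frame.

    * origin: the cup-sphere centre;
    * z: the normalised mean of the two opening-face normals, oriented
      away from the cup dome — i.e. toward the opening side, taken from
      ``opening_reference`` (a world point on the opening side; defaults
      to the mean of the two plane centroids, which for a chamfered rim
      lies off the cup centre toward the opening);
    * x: the unit direction of the intersection line of the two faces
      (``n1 x n2``), projected orthogonal to z — deterministic and
      rigid-motion equivariant because the plane labels fix the order of
      the cross product;
    * y = z x x (right-handed).

    When the faces are parallel within ``PARALLEL_PLANES_DEG`` the
    intersection line is undefined; with ``allow_azimuth_fallback`` the
    azimuth is taken from the world +x axis projected into the opening
    plane (arbitrary but deterministic), otherwise
    :class:`DegenerateAzimuthError` is raised.
    """
    origin = np.asarray(cup_sphere.center, float)
    n1 = _normalize(np.asarray(plane1.normal, float))
    n2 = np.asarray(plane2.normal, float)
    if n1 @ n2 < 0:  # make the two normals point to the same half-space
        n2 = -n2
    n2 = _normalize(n2)

    z = _normalize(n1 + n2)
    if opening_reference is None:
        opening_reference = 0.5 * (plane1.centroid + plane2.centroid)
    side = (np.asarray(opening_reference, float) - origin) @ z
    if side < 0:
        z, n1, n2 = -z, -n1, -n2

    cross = np.cross(n1, n2)
    sin_angle = np.linalg.norm(cross)
    if sin_angle >= np.sin(np.deg2rad(PARALLEL_PLANES_DEG)):
        x = cross / sin_angle
    elif allow_azimuth_fallback:
        x = np.array([1.0, 0.0, 0.0])
        if abs(x @ z) > 0.99:
            x = np.array([0.0, 1.0, 0.0])
    else:
        raise DegenerateAzimuthError(
            "opening faces are parallel within "
            f"{PARALLEL_PLANES_DEG} degree; no intersection-line azimuth"
        )
    x = _normalize(x - (x @ z) * z)
    y = np.cross(z, x)
    return CupFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def frame_transform(from_frame: CupFrame, to_frame: CupFrame) -> RigidTransform:
    """Rigid transform carrying ``from_frame`` onto ``to_frame``.

    The returned transform maps a world point ``p`` to the world point
    ``q`` whose coordinates relative to ``to_frame`` equal the
    coordinates of ``p`` relative to ``from_frame``.
    """
    Rf, Rt = from_frame.rotation, to_frame.rotation
    R = Rt @ Rf.T
    t = to_frame.origin - R @ from_frame.origin
    return RigidTransform(R, t)
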