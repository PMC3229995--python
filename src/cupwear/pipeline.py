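"""Linear-wear measurement pipelines.

Two variants are provided:

* :func:`ct_wear` — the CT route: spheres are fitted to the cup outer
  shell and the femoral head of each scan, planes to the two cup opening
  faces; each scan gets a cup-anchored coordinate frame and the wear
  vector is the displacement of the head-sphere centre between the two
  scans, expressed in cup-frame coordinates. Because the comparison is
  made in each scan's own cup frame, the result is invariant to rigid
  repositioning of either scan (the physical analogue of moving the
  phantom between CT acquisitions).

* :func:`cmm_wear` — the tactile-probe reference route: the cup *inner*
  surface is split into the ultimately worn and unworn hemispheres; the
  frame is anchored on a sphere fitted to the unworn hemisphere and the
  wear vector is the displacement of the worn-hemisphere sphere centre.

Linear wear is the Euclidean norm of the wear vector (mm). The wear
direction is reported as the polar/azimuthal angles (theta, phi) of a
standard spherical coordinate system aligned with the cup frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, NamedTuple

import numpy as np

from .geometry import (
    DEFAULT_FILTER_THRESHOLD,
    CupFrame,
    FitDegeneracyError,
    PlaneFit,
    PointCloud,
    SphereFit,
    build_cup_frame,
    fit_plane,
    fit_sphere,
)

__all__ = [
    "ScanData",
    "WearResult",
    "WearAngles",
    "ct_wear",
    "cmm_wear",
    "wear_angles",
    "split_hemispheres",
    "wear_volume_from_mass",
    "DEFAULT_DENSITY_MG_MM3",
]

#: Density of the UHMWPE cups, mg/mm^3 (= 935 kg/m^3).
DEFAULT_DENSITY_MG_MM3 = 0.935


@dataclass(frozen=True)
class ScanData:
    """All labelled surface clouds of one scan."""

    cup_outer: PointCloud
    head: PointCloud
    plane1: PointCloud
    plane2: PointCloud
    cup_inner: PointCloud | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        for name in ("cup_outer", "head", "plane1", "plane2", "cup_inner"):
            cloud = getattr(self, name)
            if cloud is None:
                continue
            if cloud.label != name:
                raise ValueError(
                    f"cloud in field {name!r} carries label {cloud.label!r}"
                )
            if self.scan_id and cloud.scan_id and cloud.scan_id != self.scan_id:
                raise ValueError(
                    f"cloud {name!r} has scan_id {cloud.scan_id!r}, "
                    f"expected {self.scan_id!r}"
                )

    def transformed(self, transform) -> "ScanData":
        """Apply a rigid motion to every cloud of the scan."""
        return ScanData(
            cup_outer=self.cup_outer.transformed(transform),
            head=self.head.transformed(transform),
            plane1=self.plane1.transformed(transform),
            plane2=self.plane2.transformed(transform),
            cup_inner=(
                None if self.cup_inner is None else self.cup_inner.transformed(transform)
            ),
            scan_id=self.scan_id,
        )


class WearAngles(NamedTuple):
    """Spherical angles of a wear vector, degrees."""

    theta: float  #: polar angle from the cup z-axis, [0, 180]
    phi: float  #: azimuth from the cup x-axis about z, (-180, 180]
    defined: bool  #: False for a (numerically) zero wear vector


@dataclass(frozen=True)
class WearResult:
    """Linear wear measurement between an unworn and a worn scan.

    ``linear_wear`` (mm) is the norm of ``wear_vector`` (cup-frame
    coordinates, mm). ``angles_defined`` is False when the wear vector
    is numerically zero, in which case theta/phi are reported as the
    conventional 0 rather than NaN.
    """

    linear_wear: float
    wear_vector: np.ndarray
    theta: float
    phi: float
    method: str
    angles_defined: bool = True
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.wear_vector, float).reshape(3)
        object.__setattr__(self, "wear_vector", v)
        if abs(np.linalg.norm(v) - self.linear_wear) > 1e-9:
            raise ValueError("linear_wear must equal |wear_vector|")


def wear_angles(wear_vector: np.ndarray, zero_tol: float = 1e-12) -> WearAngles:
    """Spherical angles (degrees) of a wear vector in cup-frame coordinates.

    theta is the polar angle from the +z axis in [0, 180]; phi the
    azimuth from +x, counter-clockwise about z, in (-180, 180]. A zero
    vector has no direction: the angles are flagged undefined and
    reported as the conventional 0. At the poles phi is likewise
    reported as 0 by convention.
    """
    v = np.asarray(wear_vector, float).reshape(3)
    r = float(np.linalg.norm(v))
    if r <= zero_tol:
        return WearAngles(0.0, 0.0, False)
    theta = math.degrees(math.acos(min(1.0, max(-1.0, v[2] / r))))
    phi = math.degrees(math.atan2(v[1], v[0]))
    if phi <= -180.0:
        phi += 360.0
    return WearAngles(theta, phi, True)


def _sphere_summary(fit: SphereFit) -> dict[str, Any]:
    return {
        "center_mm": fit.center.tolist(),
        "radius_mm": fit.radius,
        "diameter_mm": fit.diameter,
        "rms_residual_mm": fit.rms_residual,
        "n_used": fit.n_used,
        "n_rejected": fit.n_rejected,
    }


def _plane_summary(fit: PlaneFit) -> dict[str, Any]:
    return {
        "normal": fit.normal.tolist(),
        "offset_mm": fit.offset,
        "rms_residual_mm": fit.rms_residual,
        "n_used": fit.n_used,
        "n_rejected": fit.n_rejected,
    }


def _fit_or_raise(fit_fn, cloud: PointCloud, surface: str, scan: str, **kw):
    try:
        return fit_fn(cloud, **kw)
    except FitDegeneracyError as exc:
        raise FitDegeneracyError(
            f"{surface} surface of scan {scan!r}: {exc}"
        ) from exc


def _scan_frame(
    scan: ScanData, filter_threshold: float
) -> tuple[CupFrame, SphereFit, PlaneFit, PlaneFit]:
    """Fit cup sphere and opening faces of one scan and build its frame."""
    cup = _fit_or_raise(
        fit_sphere, scan.cup_outer, "cup_outer", scan.scan_id,
        filter_threshold=filter_threshold,
    )
    # orient each face normal away from the dome: the head sits in the
    # cup toward the opening, so its centroid is a robust opening-side
    # reference available in every scan
    opening_ref = scan.head.points.mean(axis=0)
    p1 = _fit_or_raise(
        fit_plane, scan.plane1, "plane1", scan.scan_id,
        filter_threshold=filter_threshold, positive_side=opening_ref,
    )
    p2 = _fit_or_raise(
        fit_plane, scan.plane2, "plane2", scan.scan_id,
        filter_threshold=filter_threshold, positive_side=opening_ref,
    )
    frame = build_cup_frame(cup, p1, p2, opening_reference=opening_ref)
    return frame, cup, p1, p2


def ct_wear(
    pre: ScanData,
    post: ScanData,
    filter_threshold: float = DEFAULT_FILTER_THRESHOLD,
) -> WearResult:
    """Measure femoral-head penetration between two CT scans.

    Fits the cup-outer sphere, head sphere and both opening-face planes
    of each scan (with artifact elimination at ``filter_threshold`` mm),
    builds each scan's cup frame, and takes the wear vector as the
    difference of the head-sphere centres expressed in their own cup
    frames. The result is independent of any rigid motion applied to
    either scan's raw coordinates.
    """
    heads: dict[str, np.ndarray] = {}
    diagnostics: dict[str, Any] = {}
    for name, scan in (("pre", pre), ("post", post)):
        frame, cup, p1, p2 = _scan_frame(scan, filter_threshold)
        head = _fit_or_raise(
            fit_sphere, scan.head, "head", scan.scan_id,
            filter_threshold=filter_threshold,
        )
        heads[name] = frame.to_local(head.center[None, :])[0]
        diagnostics[name] = {
            "cup_outer": _sphere_summary(cup),
            "head": _sphere_summary(head),
            "plane1": _plane_summary(p1),
            "plane2": _plane_summary(p2),
        }
    vector = heads["post"] - heads["pre"]
    wear = float(np.linalg.norm(vector))
    angles = wear_angles(vector)
    return WearResult(
        linear_wear=wear,
        wear_vector=vector,
        theta=angles.theta,
        phi=angles.phi,
        method="CT",
        angles_defined=angles.defined,
        diagnostics=diagnostics,
    )


def split_hemispheres(
    inner: PointCloud, frame: CupFrame, flip: bool = False
) -> tuple[PointCloud, PointCloud]:
    """Partition a cup-inner cloud into worn and unworn hemispheres.

    The hip simulator loads the cup asymmetrically, so wear concentrates
    on one side of the inner surface. Points with cup-frame x >= 0 form
    the worn side (``flip=True`` swaps the convention for mirrored,
    left-sided cups). Returns ``(worn_side, unworn_side)``; every input
    point lands in exactly one output, order preserved.
    """
    x_local = frame.to_local(inner.points)[:, 0]
    worn_mask = x_local >= 0
    if flip:
        worn_mask = ~worn_mask
    return inner.subset(worn_mask), inner.subset(~worn_mask)


def cmm_wear(
    pre_inner: PointCloud,
    post_inner: PointCloud,
    pre_planes: tuple[PointCloud, PointCloud],
    post_planes: tuple[PointCloud, PointCloud],
    filter_threshold: float = DEFAULT_FILTER_THRESHOLD,
    flip_worn_side: bool = False,
) -> WearResult:
    """Measure wear from the cup inner surface, tactile-probe style.

    Per scan: the opening-face planes give the frame axes; a sphere
    fitted to the ultimately *unworn* hemisphere of the inner surface
    anchors the frame origin; a second sphere is fitted to the worn
    hemisphere. The wear vector is the displacement of the worn-
    hemisphere sphere centre between scans, expressed in the common
    cup frame.
    """
    centers: dict[str, np.ndarray] = {}
    diagnostics: dict[str, Any] = {}
    for name, inner, planes in (
        ("pre", pre_inner, pre_planes),
        ("post", post_inner, post_planes),
    ):
        scan_id = inner.scan_id
        # provisional sphere on the whole inner surface fixes the frame
        # origin well enough to split the hemispheres
        whole = _fit_or_raise(
            fit_sphere, inner, "cup_inner", scan_id,
            filter_threshold=filter_threshold,
        )
        # the inner-surface centroid sits on the dome side of the cup
        # centre; its reflection through the centre marks the opening side
        opening_ref = 2.0 * whole.center - inner.points.mean(axis=0)
        p1 = _fit_or_raise(
            fit_plane, planes[0], "plane1", scan_id,
            filter_threshold=filter_threshold, positive_side=opening_ref,
        )
        p2 = _fit_or_raise(
            fit_plane, planes[1], "plane2", scan_id,
            filter_threshold=filter_threshold, positive_side=opening_ref,
        )
        frame0 = build_cup_frame(whole, p1, p2, opening_reference=opening_ref)
        worn_cloud, unworn_cloud = split_hemispheres(inner, frame0, flip=flip_worn_side)
        if len(worn_cloud) < 4 or len(unworn_cloud) < 4:
            raise FitDegeneracyError(
                f"cup_inner of scan {scan_id!r}: a hemisphere has fewer than "
                "4 points after splitting"
            )
        unworn = _fit_or_raise(
            fit_sphere, unworn_cloud, "cup_inner (unworn side)", scan_id,
            filter_threshold=filter_threshold,
        )
        worn = _fit_or_raise(
            fit_sphere, worn_cloud, "cup_inner (worn side)", scan_id,
            filter_threshold=filter_threshold,
        )
        frame = build_cup_frame(unworn, p1, p2, opening_reference=opening_ref)
        centers[name] = frame.to_local(worn.center[None, :])[0]
        diagnostics[name] = {
            "cup_inner_unworn": _sphere_summary(unworn),
            "cup_inner_worn": _sphere_summary(worn),
            "plane1": _plane_summary(p1),
            "plane2": _plane_summary(p2),
        }
    vector = centers["post"] - centers["pre"]
    wear = float(np.linalg.norm(vector))
    angles = wear_angles(vector)
    return WearResult(
        linear_wear=wear,
        wear_vector=vector,
        theta=angles.theta,
        phi=angles.phi,
        method="CMM",
        angles_defined=angles.defined,
        diagnostics=diagnostics,
    )


def wear_volume_from_mass(
    mass_loss_mg: float, density_mg_mm3: float = DEFAULT_DENSITY_MG_MM3
) -> float:
    """Convert gravimetric mass loss (mg) to wear volume (mm^3).

    Default density 0.935 mg/mm^3 corresponds to the UHMWPE cups.
    Negative mass loss (fluid soak gain exceeding wear) yields a
    negative volume.
    """
    if density_mg_mm3 <= 0:
        raise ValueError("density must be positive")
    return mass_loss_mg / density_mg_mm3
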