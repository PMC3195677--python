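"""Acetabular coordinate frame: sphere fit, rim plane, anatomical axes.

The joint center is located by least-squares sphere fitting on the outlined
acetabular region of the reconstructed bone. A total-least-squares plane is
fit to the rim outline; the acetabular axis ``n`` is the rim-plane normal
through the sphere center, signed to point laterally (out of the socket).
The in-plane anteroposterior axis comes from the pelvic landmarks (the two
anterior superior iliac spines and a pubis point) following the ISB pelvic
coordinate conventions, projected into the rim plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError, FrameError

_UNIT_TOL = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise DegenerateGeometryError("zero-length vector")
    return v / n


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere: center (mm), radius (mm), rms residual (mm)."""

    center: np.ndarray
    radius: float
    rms_residual: float


@dataclass(frozen=True)
class RimPlane:
    """Plane through the acetabular rim: a point (the rim centroid) and a
    unit normal (sign not anatomically resolved; see AcetabularFrame.n)."""

    point: np.ndarray
    normal: np.ndarray


@dataclass(frozen=True)
class AcetabularFrame:
    """Orthonormal frame of the reconstructed acetabulum.

    center : joint center (fitted sphere center), mm
    n : unit acetabular axis, pointing laterally (out of the cup)
    rim_plane : the fitted rim plane
    ap_axis : unit vector in the rim plane pointing anterior
    sup_axis : unit vector in the rim plane pointing superior
    side : "left" or "right"
    """

    center: np.ndarray
    n: np.ndarray
    rim_plane: RimPlane
    ap_axis: np.ndarray
    sup_axis: np.ndarray
    side: str
    warnings: tuple = field(default=())


def fit_sphere(points) -> SphereFit:
    """Least-squares sphere fit to >= 4 non-coplanar points.

    An algebraic (linear) fit provides the initial estimate; a geometric
    Gauss-Newton refinement then minimizes sum(|p - c| - r)^2 to a 1e-9 mm
    tolerance. The rms residual is the root mean square of |p - c| - r.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(p) < 4:
        raise DegenerateGeometryError(f"sphere fit needs >= 4 points, got {len(p)}")
    c = p - p.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[2] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("sphere fit needs non-coplanar points")

    # algebraic fit: |p|^2 = 2 p.c + (r^2 - |c|^2), linear in (c, k)
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 0.0)))

    def residual(x):
        d = np.linalg.norm(p - x[:3], axis=1)
        return d - x[3]

    def jac(x):
        diff = p - x[:3]
        d = np.linalg.norm(diff, axis=1)
        J = np.empty((len(p), 4))
        J[:, :3] = -diff / d[:, None]
        J[:, 3] = -1.0
        return J

    fit = least_squares(residual, np.append(c0, r0), jac=jac, method="lm",
                        xtol=1e-12, ftol=1e-15, gtol=1e-15)
    center = fit.x[:3]
    radius = float(fit.x[3])
    res = residual(fit.x)
    return SphereFit(center=center, radius=radius,
                     rms_residual=float(np.sqrt(np.mean(res**2))))


def fit_rim_plane(rim_points) -> RimPlane:
    """Total-least-squares plane through the rim outline.

    The plane point is the centroid; the normal is the smallest principal
    component of the centered points. The normal's sign carries no anatomy.
    """
    p = np.asarray(rim_points, dtype=float).reshape(-1, 3)
    if len(p) < 3:
        raise DegenerateGeometryError(f"plane fit needs >= 3 points, got {len(p)}")
    centroid = p.mean(axis=0)
    c = p - centroid
    _, s, vt = np.linalg.svd(c, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("plane fit needs non-collinear points")
    normal = _unit(vt[2])
    return RimPlane(point=centroid, normal=normal)


def pelvic_axes(landmarks: dict) -> dict:
    """ISB-style pelvic axes from the ASIS line and the pubis point.

    Returns unit vectors:
      ml  : mediolateral, from left ASIS toward right ASIS
      ant : anterior, orthogonal to ml within the plane through both ASIS
            and the pubis point, pointing toward the pubis side
      sup : superior, completing the right-handed (ant, sup, ml) triad
            (ant x sup = ml, i.e. sup = ml x ant)
    """
    try:
        asis_l = np.asarray(landmarks["asis_left"], dtype=float)
        asis_r = np.asarray(landmarks["asis_right"], dtype=float)
        pubis = np.asarray(landmarks["pubis"], dtype=float)
    except KeyError as exc:
        raise FrameError(f"missing landmark {exc}") from exc
    ml = _unit(asis_r - asis_l)
    mid = 0.5 * (asis_l + asis_r)
    u = pubis - mid
    in_plane = u - (u @ ml) * ml
    if np.linalg.norm(in_plane) < 1e-9:
        raise FrameError("pubis point lies on the ASIS line; landmarks collinear")
    ant = _unit(in_plane)
    sup = np.cross(ml, ant)
    return {"ml": ml, "ant": ant, "sup": sup, "asis_mid": mid}


def build_frame(sphere: SphereFit, plane: RimPlane, landmarks: dict, side: str) -> AcetabularFrame:
    """Assemble the acetabular frame.

    The acetabular axis ``n`` is the rim-plane normal signed so that it
    points laterally; lateral is taken as the direction from the ASIS
    midpoint toward the sphere center, projected onto the plane normal.
    The anteroposterior axis is the pelvic anterior axis projected into the
    rim plane; the superior in-plane axis is ``n x ap`` for a right side
    and ``-(n x ap)`` for a left side, which points superiorly when side
    flag and geometry agree.
    """
    if side not in ("left", "right"):
        raise FrameError(f"side must be 'left' or 'right', got {side!r}")
    axes = pelvic_axes(landmarks)
    lateral_ref = sphere.center - axes["asis_mid"]
    sgn = lateral_ref @ plane.normal
    if sgn == 0:
        raise FrameError("cannot resolve lateral direction: center on ASIS-midpoint plane")
    n = _unit(plane.normal * np.sign(sgn))

    ant = axes["ant"]
    in_plane = ant - (ant @ n) * n
    # degenerate when the anterior axis is within ~1 degree of the axis n
    if np.linalg.norm(in_plane) < np.sin(np.deg2rad(1.0)):
        raise FrameError("anterior axis nearly parallel to the acetabular axis")
    ap = _unit(in_plane)
    sup = np.cross(n, ap)
    if side == "left":
        sup = -sup

    warnings = []
    sup_ref = axes["sup"] - (axes["sup"] @ n) * n
    if np.linalg.norm(sup_ref) > 1e-9 and sup @ _unit(sup_ref) < 0:
        warnings.append(
            "side flag and landmark geometry disagree: in-plane superior axis "
            "points away from the pelvic superior direction"
        )
    return AcetabularFrame(center=np.asarray(sphere.center, dtype=float), n=n,
                           rim_plane=plane, ap_axis=ap, sup_axis=sup, side=side,
                           warnings=tuple(warnings))


def frame_from_case(reconstructed, config) -> tuple[AcetabularFrame, SphereFit]:
    """Convenience: fit sphere and rim plane from a CaseConfig and build the frame."""
    sphere = fit_sphere(config.acetabular_region)
    plane = fit_rim_plane(config.rim_outline)
    frame = build_frame(sphere, plane, config.landmarks, config.side)
    return frame, sphere
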