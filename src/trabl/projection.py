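"""Azimuthal equidistant unfolding of the spherical grid and the bone-loss ratio.

The spherical grid is unfolded into the plane by the azimuthal equidistant
projection: planar radius r = r_u * phi (arc length from the pole at the
inward acetabular axis), x = r cos(theta), y = r sin(theta). Two planar
surfaces are measured on this grid: the one enclosed by grid points whose
rays intersect the reconstructed mesh (area A_rec) and the one for the
deficient mesh (A_def). The total radial bone-loss ratio is

    ratio = (1 - A_def / A_rec) * 100 %

evaluated globally and per anatomical region. Areas are measured in the
distorted planar metric of the projection (an opt-in flag measures them on
the sphere instead). Discrete areas use per-cell shoelace areas with
fractional corner weighting (k/4 for k masked corners); an all-corner cell
membership rule is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedRatioError
from .grid import SphericalGrid
from .raycast import DeviationMap
from .regions import REGION_ORDER, RegionLabels


@dataclass(frozen=True)
class PlanarMap:
    """Planar coordinates of every grid point (azimuthal equidistant)."""

    x: np.ndarray
    y: np.ndarray
    r: np.ndarray


@dataclass(frozen=True)
class RegionResult:
    """Areas (mm^2 of planar grid) and ratio (%) of one region; ratio is
    None where the region has no reconstructed-mesh hits (not assessable)."""

    A_rec: float
    A_def: float
    ratio: float | None


@dataclass(frozen=True)
class TrABLResult:
    """Global and per-region radial bone-loss result."""

    A_rec: float
    A_def: float
    ratio: float
    per_region: dict
    metadata: dict = field(default_factory=dict)


def project_to_plane(grid: SphericalGrid) -> PlanarMap:
    """Unfold the spherical grid into the planar azimuthal grid."""
    r = grid.r_u * grid.phi[:, None] * np.ones((1, len(grid.theta)))
    x = r * np.cos(grid.theta)[None, :]
    y = r * np.sin(grid.theta)[None, :]
    return PlanarMap(x=x, y=y, r=r)


def cell_areas(planar: PlanarMap, metric: str = "planar",
               phi: np.ndarray | None = None) -> np.ndarray:
    """Shoelace area of every grid cell, shape (n_phi - 1, n_theta).

    Cells are quadrilaterals of index-adjacent points; the azimuth is
    periodic, so column j pairs with column (j + 1) mod n_theta and the
    last column closes the seam. With metric="spherical" the true spherical
    quad area (r_u^2 * dtheta * |cos phi_i - cos phi_i+1|) is used instead;
    this requires *phi*.
    """
    if metric == "spherical":
        if phi is None:
            raise ValueError("spherical metric needs the phi samples")
        n_theta = planar.x.shape[1]
        dtheta = 2.0 * np.pi / n_theta
        band = np.abs(np.cos(phi[:-1]) - np.cos(phi[1:])) * dtheta
        return np.repeat(band[:, None], n_theta, axis=1)
    x, y = planar.x, planar.y
    nxt = np.roll(np.arange(x.shape[1]), -1)
    # corners in cyclic order: (i,j), (i,j+1), (i+1,j+1), (i+1,j)
    xs = np.stack([x[:-1], x[:-1][:, nxt], x[1:][:, nxt], x[1:]])
    ys = np.stack([y[:-1], y[:-1][:, nxt], y[1:][:, nxt], y[1:]])
    area2 = np.zeros_like(xs[0])
    for a in range(4):
        b = (a + 1) % 4
        area2 += xs[a] * ys[b] - xs[b] * ys[a]
    return 0.5 * np.abs(area2)


def corner_fractions(mask: np.ndarray) -> np.ndarray:
    """Fraction of masked corners per cell (k/4), shape (n_phi-1, n_theta)."""
    m = mask.astype(float)
    nxt = np.roll(np.arange(mask.shape[1]), -1)
    return 0.25 * (m[:-1] + m[:-1][:, nxt] + m[1:][:, nxt] + m[1:])


def _all_corners(mask: np.ndarray) -> np.ndarray:
    nxt = np.roll(np.arange(mask.shape[1]), -1)
    return mask[:-1] & mask[:-1][:, nxt] & mask[1:][:, nxt] & mask[1:]


def masked_area(planar: PlanarMap, mask: np.ndarray, region_filter: np.ndarray | None = None,
                membership: str = "fractional", metric: str = "planar",
                phi: np.ndarray | None = None) -> float:
    """Planar surface area enclosed by the masked grid points.

    Parameters
    ----------
    mask : boolean per grid point (e.g. the hit flags)
    region_filter : optional boolean per grid point; a cell contributes only
        when all four of its corners pass the filter
    membership : "fractional" weights each cell by masked-corners/4;
        "all_corners" counts a cell only when all four corners are masked
    metric : "planar" (default) or "spherical"
    """
    mask = np.asarray(mask, dtype=bool)
    areas = cell_areas(planar, metric=metric, phi=phi)
    if membership == "fractional":
        w = corner_fractions(mask)
    elif membership == "all_corners":
        w = _all_corners(mask).astype(float)
    else:
        raise ValueError(f"unknown membership rule {membership!r}")
    if region_filter is not None:
        w = w * _all_corners(np.asarray(region_filter, dtype=bool))
    return float((areas * w).sum())


def trabl_ratio(A_def: float, A_rec: float) -> float:
    """Total radial bone-loss ratio (1 - A_def/A_rec) * 100, in percent.

    Not clamped: deficient bone protruding beyond the reconstruction can
    make A_def exceed A_rec and the ratio negative.
    """
    if A_rec <= 0:
        raise UndefinedRatioError("reference area A_rec is zero; ratio undefined")
    return (1.0 - A_def / A_rec) * 100.0


def evaluate(deviation: DeviationMap, planar: PlanarMap, labels: RegionLabels,
             metric: str = "planar", phi: np.ndarray | None = None) -> TrABLResult:
    """Compute areas and ratios, globally and per region.

    Per-cell region membership (evaluated at the cell centroid) partitions
    the grid, so region areas sum exactly to the global areas. A region
    without reconstructed-mesh hits is flagged not assessable (ratio None);
    a negative global or regional ratio is reported as computed, with a
    warning in the metadata.
    """
    areas = cell_areas(planar, metric=metric, phi=phi)
    w_rec = corner_fractions(deviation.hit_rec)
    w_def = corner_fractions(deviation.hit_def)
    meta_warnings = list(deviation.warnings)

    per_region = {}
    A_rec_total = 0.0
    A_def_total = 0.0
    for i, name in enumerate(REGION_ORDER):
        in_region = labels.cell_codes == i
        a_rec = float((areas * w_rec * in_region).sum())
        a_def = float((areas * w_def * in_region).sum())
        A_rec_total += a_rec
        A_def_total += a_def
        if a_rec <= 0.0:
            per_region[name] = RegionResult(A_rec=a_rec, A_def=a_def, ratio=None)
            meta_warnings.append(f"region {name} has no reconstructed-surface area; not assessable")
        else:
            r = trabl_ratio(a_def, a_rec)
            if r < 0:
                meta_warnings.append(
                    f"region {name}: deficient area exceeds reconstructed area (ratio {r:.1f}%)")
            per_region[name] = RegionResult(A_rec=a_rec, A_def=a_def, ratio=r)

    if A_rec_total <= 0.0:
        raise UndefinedRatioError("no rays intersect the reconstructed mesh")
    global_ratio = trabl_ratio(A_def_total, A_rec_total)
    if global_ratio < 0:
        meta_warnings.append(f"global deficient area exceeds reconstructed area "
                             f"(ratio {global_ratio:.1f}%)")
    return TrABLResult(A_rec=A_rec_total, A_def=A_def_total, ratio=global_ratio,
                       per_region=per_region,
                       metadata={"grid_shape": deviation.hit_rec.shape,
                                 "metric": metric,
                                 "warnings": meta_warnings})
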