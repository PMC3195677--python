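"""Anatomical subregions of the acetabular grid.

Six regions: a medial cap (Med) of all unit-sphere grid points lying within
half the unit radius of the acetabular axis on the medial side (sin(phi) <=
1/2 and phi <= pi/2, i.e. phi <= pi/6), and five 72-degree sectors spread
equally around the projected anteroposterior axis: posteroinferior,
inferior, anteroinferior, anterosuperior and posterosuperior. The in-plane
angle psi is measured from the anterior axis toward the superior axis, so a
single interval table serves both sides (handedness is absorbed by the
frame construction). The anterior direction is the AntSup/AntInf boundary;
the sector boundaries can be rotated with ``sector_offset_deg`` since their
exact placement is a convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import SphericalGrid

#: serialized region order (sectors first, medial cap last)
REGION_ORDER = ("PostInf", "Inf", "AntInf", "AntSup", "PostSup", "Med")
#: the five sectors in radar-plot order
SECTOR_ORDER = ("PostInf", "Inf", "AntInf", "AntSup", "PostSup")

# sector table: label -> [psi_lo, psi_hi) in degrees, psi from ap toward sup
SECTOR_INTERVALS = {
    "AntSup": (0.0, 72.0),
    "PostSup": (72.0, 144.0),
    "PostInf": (144.0, 216.0),
    "Inf": (216.0, 288.0),
    "AntInf": (288.0, 360.0),
}

_MED = REGION_ORDER.index("Med")
_BOUNDARY_TOL = 1e-12


@dataclass(frozen=True)
class RegionLabels:
    """Per-grid-point region labels.

    codes : (n_phi, n_theta) int indices into REGION_ORDER
    cell_codes : (n_phi - 1, n_theta) int region index of each grid cell,
        evaluated at the cell centroid so that the cells of the six regions
        partition the grid exactly
    sector_offset_deg : boundary rotation used when assigning
    """

    codes: np.ndarray
    cell_codes: np.ndarray
    sector_offset_deg: float = 0.0

    @property
    def names(self) -> tuple:
        return REGION_ORDER

    def mask(self, name: str) -> np.ndarray:
        return self.codes == REGION_ORDER.index(name)

    def cell_mask(self, name: str) -> np.ndarray:
        return self.cell_codes == REGION_ORDER.index(name)


def _label_codes(phi, psi_deg, sector_offset_deg: float) -> np.ndarray:
    """Vectorised label lookup for polar angle phi and in-plane angle psi."""
    phi = np.asarray(phi, dtype=float)
    psi = np.mod(np.asarray(psi_deg, dtype=float) - sector_offset_deg, 360.0)
    # np.mod of a tiny negative angle can land exactly on 360.0
    psi = np.where(psi >= 360.0, psi - 360.0, psi)
    codes = np.empty(phi.shape, dtype=np.int8)
    sector = np.clip((psi / 72.0).astype(int), 0, 4)
    order = ("AntSup", "PostSup", "PostInf", "Inf", "AntInf")
    lut = np.array([REGION_ORDER.index(n) for n in order], dtype=np.int8)
    codes[...] = lut[sector]
    # medial cap: distance of the unit-sphere point to the axis is sin(phi);
    # boundary inclusive, restricted to the medial (phi <= pi/2) branch
    med = (np.sin(phi) <= 0.5 + _BOUNDARY_TOL) & (phi <= np.pi / 2 + _BOUNDARY_TOL)
    codes[med] = _MED
    return codes


def assign_regions(grid: SphericalGrid, sector_offset_deg: float = 0.0) -> RegionLabels:
    """Assign every grid point (and every grid cell) to one of the six regions.

    For a grid direction at (phi, theta) the projection into the rim plane
    makes the in-plane angle psi equal to theta, measured from the
    anteroposterior axis toward the superior axis.
    """
    n_phi, n_theta = grid.shape
    phi2d = np.broadcast_to(grid.phi[:, None], (n_phi, n_theta))
    psi2d = np.broadcast_to(np.rad2deg(grid.theta)[None, :], (n_phi, n_theta))
    codes = _label_codes(phi2d, psi2d, sector_offset_deg)

    # cell centroids: phi midway between rows, theta midway between columns
    # (the last column wraps around the -pi/pi seam)
    phi_mid = 0.5 * (grid.phi[:-1] + grid.phi[1:])
    dtheta = 2.0 * np.pi / n_theta
    theta_mid = grid.theta + 0.5 * dtheta
    pm = np.broadcast_to(phi_mid[:, None], (n_phi - 1, n_theta))
    tm = np.broadcast_to(np.rad2deg(theta_mid)[None, :], (n_phi - 1, n_theta))
    cell_codes = _label_codes(pm, tm, sector_offset_deg)
    return RegionLabels(codes=codes, cell_codes=cell_codes,
                        sector_offset_deg=sector_offset_deg)


def region_fractions(labels: RegionLabels, planar, within=None) -> dict:
    """Planar-area fraction of each region.

    Parameters
    ----------
    labels : RegionLabels
    planar : PlanarMap
    within : optional boolean per grid point restricting the tally
        (e.g. the r <= pi/2 disk); defaults to the whole grid.

    Returns
    -------
    dict region name -> fraction of the (restricted) planar area
    """
    from .projection import cell_areas, corner_fractions

    areas = cell_areas(planar)
    if within is None:
        w = np.ones_like(areas)
    else:
        w = corner_fractions(np.asarray(within, dtype=bool))
    total = float((areas * w).sum())
    out = {}
    for i, name in enumerate(REGION_ORDER):
        out[name] = float((areas * w * (labels.cell_codes == i)).sum()) / total
    return out
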