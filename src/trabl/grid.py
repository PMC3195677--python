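"""Uniform spherical ray grid in the acetabular frame.

Rays emanate from the joint center along directions parameterised by a
polar angle phi in [0, pi] measured from the inward acetabular axis -n
(phi = 0 points into the middle of the cup) and an azimuth theta in
[-pi, pi) measured from the anteroposterior axis toward the superior
in-plane axis, on a unit sphere of radius r_u = 1 mm:

    d(phi, theta) = -cos(phi) n + sin(phi) (cos(theta) ap + sin(theta) sup)

The default sampling is the fixed 100 x 100 grid used for inter-case
comparison. phi is sampled closed on [0, pi] (the poles collapse to single
directions but are retained for grid regularity); theta is sampled
half-open on [-pi, pi) to avoid duplicating the antipodal column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frame import AcetabularFrame

#: radius of the reference unit sphere, mm
R_U = 1.0


@dataclass(frozen=True)
class SphericalGrid:
    """The phi x theta ray grid.

    phi : (n_phi,) polar angles, uniform closed on [0, pi]
    theta : (n_theta,) azimuths, uniform half-open on [-pi, pi)
    directions : (n_phi, n_theta, 3) unit ray directions in world frame
    origin : (3,) common ray origin (the joint center), mm
    frame : the acetabular frame the grid was built in
    """

    phi: np.ndarray
    theta: np.ndarray
    directions: np.ndarray
    origin: np.ndarray
    frame: AcetabularFrame
    r_u: float = R_U

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.phi), len(self.theta)

    @property
    def n_points(self) -> int:
        return len(self.phi) * len(self.theta)


def build_grid(frame: AcetabularFrame, n_phi: int = 100, n_theta: int = 100) -> SphericalGrid:
    """Build the spherical ray grid for *frame*."""
    if n_phi < 2 or n_theta < 2:
        raise ValueError("grid needs n_phi >= 2 and n_theta >= 2")
    phi = np.linspace(0.0, np.pi, n_phi)
    theta = -np.pi + 2.0 * np.pi * np.arange(n_theta) / n_theta
    sp, st = np.sin(phi)[:, None], np.sin(theta)[None, :]
    cp, ct = np.cos(phi)[:, None], np.cos(theta)[None, :]
    d = (-cp[..., None] * frame.n
         + sp[..., None] * (ct[..., None] * frame.ap_axis + st[..., None] * frame.sup_axis))
    # normalise away rounding; poles are exact by construction (sin 0 = 0)
    d /= np.linalg.norm(d, axis=2, keepdims=True)
    return SphericalGrid(phi=phi, theta=theta, directions=d,
                         origin=np.asarray(frame.center, dtype=float), frame=frame)
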