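"""Standalone brute-force verification path.

This module recomputes bone-loss ratios with deliberately plain code that
shares nothing with the main pipeline: directions are rebuilt from scratch,
every ray is tested against every triangle in a per-ray Moller-Trumbore
loop (no precomputation, no spatial acceleration), planar cell areas use
the strict all-corner membership rule, and region labels are re-derived
from first principles. It exists purely as an independent oracle for tests
and acceptance checks; it is slow by design.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-6


def brute_force_first_hit(origin, direction, triangles):
    """Smallest positive hit parameter of one ray over all *triangles*
    ((m, 3, 3) array), or None. Textbook Moller-Trumbore, unoriented."""
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    best = np.inf
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    pvec = np.cross(np.broadcast_to(d, e2.shape), e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-14
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.dot(qvec, d) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1.0 + 1e-12) & (t > _EPS)
    if np.any(hit):
        best = t[hit].min()
    return float(best) if np.isfinite(best) else None


def _angles(n_dense):
    phis = np.pi * np.arange(n_dense) / (n_dense - 1)
    thetas = -np.pi + 2.0 * np.pi * np.arange(n_dense) / n_dense
    return phis, thetas


def _label(phi, theta_deg):
    """Region name from polar angle and azimuth (deg from anterior axis)."""
    if np.sin(phi) <= 0.5 + 1e-12 and phi <= np.pi / 2 + 1e-12:
        return "Med"
    psi = theta_deg % 360.0
    if psi >= 360.0:
        psi -= 360.0
    for name, lo, hi in (("AntSup", 0, 72), ("PostSup", 72, 144),
                         ("PostInf", 144, 216), ("Inf", 216, 288),
                         ("AntInf", 288, 360)):
        if lo <= psi < hi:
            return name
    return "AntInf"


def brute_force_ratios(deficient, reconstructed, center, n, ap, sup,
                       dense_n: int = 400) -> dict:
    """Dense independent recomputation of global and per-region ratios (%).

    Regions with no reconstructed-surface cells map to None.
    """
    center = np.asarray(center, dtype=float)
    n = np.asarray(n, dtype=float)
    ap = np.asarray(ap, dtype=float)
    sup = np.asarray(sup, dtype=float)
    phis, thetas = _angles(dense_n)

    tri_def = deficient.triangles()
    tri_rec = reconstructed.triangles()

    hit_def = np.zeros((dense_n, dense_n), dtype=bool)
    hit_rec = np.zeros((dense_n, dense_n), dtype=bool)
    for i, phi in enumerate(phis):
        for j, theta in enumerate(thetas):
            d = (-np.cos(phi) * n
                 + np.sin(phi) * (np.cos(theta) * ap + np.sin(theta) * sup))
            if len(tri_rec):
                hit_rec[i, j] = brute_force_first_hit(center, d, tri_rec) is not None
            if len(tri_def):
                hit_def[i, j] = brute_force_first_hit(center, d, tri_def) is not None

    # planar coordinates, r = phi (unit sphere)
    x = phis[:, None] * np.cos(thetas)[None, :]
    y = phis[:, None] * np.sin(thetas)[None, :]

    # per-cell quad areas (azimuth periodic) and all-corner masks
    jn = (np.arange(dense_n) + 1) % dense_n
    quad_x = (x[:-1], x[:-1][:, jn], x[1:][:, jn], x[1:])
    quad_y = (y[:-1], y[:-1][:, jn], y[1:][:, jn], y[1:])
    area2 = np.zeros_like(quad_x[0])
    for a in range(4):
        b = (a + 1) % 4
        area2 += quad_x[a] * quad_y[b] - quad_x[b] * quad_y[a]
    areas = 0.5 * np.abs(area2)

    def all_corner(mask):
        return mask[:-1] & mask[:-1][:, jn] & mask[1:][:, jn] & mask[1:]

    cell_rec = all_corner(hit_rec)
    cell_def = all_corner(hit_def)

    # cell region from its centroid angles
    phi_mid = 0.5 * (phis[:-1] + phis[1:])
    theta_mid = thetas + np.pi / dense_n
    cell_region = np.empty((dense_n - 1, dense_n), dtype=object)
    for i, pm in enumerate(phi_mid):
        for j, tm in enumerate(theta_mid):
            cell_region[i, j] = _label(pm, np.rad2deg(tm))

    out = {}
    a_rec_tot = a_def_tot = 0.0
    for name in ("PostInf", "Inf", "AntInf", "AntSup", "PostSup", "Med"):
        sel = cell_region == name
        a_rec = float(areas[sel & cell_rec].sum())
        a_def = float(areas[sel & cell_def].sum())
        a_rec_tot += a_rec
        a_def_tot += a_def
        out[name] = None if a_rec == 0.0 else (1.0 - a_def / a_rec) * 100.0
    out["global"] = (1.0 - a_def_tot / a_rec_tot) * 100.0
    return out
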