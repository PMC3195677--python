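"""Synthetic acetabular phantoms with known ground-truth bone loss.

A phantom is a hemispherical cup shell: an inner spherical surface of
radius ``cavity_radius``, an outer surface at ``cavity_radius +
shell_thickness`` and a flat annulus closing the shell at the rim plane.
The cup is tessellated on a structured latitude/longitude grid so that the
rim circle and angular defect windows fall exactly on mesh edges and the
analytic loss expectations are exact. Defects are applied to a copy of the
reconstructed shell:

- ``theta_wedge`` deletes all faces whose centroid azimuth lies in a range,
  through the full shell thickness (an uncontained radial wedge defect);
- ``cap_hole`` deletes all faces with centroid polar angle below a bound
  (a medial perforation);
- ``erosion`` displaces inner-surface vertices radially outward by a depth
  within an angular window (cavity erosion without total loss).

Face deletion (rather than boolean CSG) leaves no cut walls, so radial
rays see exactly the analytic angular fractions. Landmarks are placed so
that the anatomical frame comes out axis-aligned: the acetabular axis is
+Z, anterior +X, superior +Y (for a right-sided phantom) in the phantom's
local coordinates, optionally rigidly transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import PhantomError
from .frame import AcetabularFrame, RimPlane, SphereFit
from .io import CaseConfig, TriangleMesh, write_case_config, write_mesh

DEFECT_KINDS = ("theta_wedge", "cap_hole", "erosion")


@dataclass(frozen=True)
class DefectOp:
    """One defect operation; params depend on kind (angles rad, depth mm)."""

    kind: str
    params: dict

    def __post_init__(self):
        if self.kind not in DEFECT_KINDS:
            raise PhantomError(f"unknown defect kind {self.kind!r}")
        if self.kind == "erosion" and self.params.get("depth", 0.0) <= 0:
            raise PhantomError("erosion depth must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one phantom pair.

    cavity_radius : inner (joint) radius, mm — default 24 mm, a typical
        adult acetabular radius
    shell_thickness : shell wall thickness, mm
    tessellation_level : L >= 2; the cup uses 6L latitude rows and 24L
        azimuth columns per surface
    defects : defect operations applied to the deficient copy
    detached_band : optional dict(radius, phi_range, theta_range) adding a
        detached spherical band beyond the rim to BOTH meshes (emulates
        bone re-detected through the obturator foramen)
    empty_deficient : if True the deficient mesh has no geometry at all
        (total resection; every ray deviation is infinite)
    center : cup center in world coordinates, mm
    side : "left" or "right"
    rotation : optional (3, 3) rotation applied to all geometry about center
    seed : controls the sampled acetabular-region vertex subset
    """

    cavity_radius: float = 24.0
    shell_thickness: float = 5.0
    tessellation_level: int = 2
    defects: tuple = ()
    detached_band: dict | None = None
    empty_deficient: bool = False
    center: tuple = (0.0, 0.0, 0.0)
    side: str = "right"
    rotation: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.cavity_radius <= 0 or self.shell_thickness <= 0:
            raise PhantomError("cavity_radius and shell_thickness must be > 0")
        if self.tessellation_level < 2:
            raise PhantomError("tessellation_level must be >= 2")


def _cup_direction(alpha, theta):
    """Unit direction at polar angle alpha from the -Z pole."""
    alpha, theta = np.broadcast_arrays(np.asarray(alpha, float), np.asarray(theta, float))
    sa, ca = np.sin(alpha), np.cos(alpha)
    return np.stack([sa * np.cos(theta), sa * np.sin(theta), -ca], axis=-1)


def _spherical_patch(radius, alphas, thetas, closed_pole=False):
    """Structured triangulated patch of a sphere. Returns (verts, faces)."""
    n_t = len(thetas)
    verts = []
    rows = []
    start_row = 0
    if closed_pole:
        verts.append(np.array([[0.0, 0.0, -radius]]))
        start_row = 1
    for a in alphas[start_row:] if closed_pole else alphas:
        verts.append(radius * _cup_direction(a, thetas))
    verts = np.concatenate(verts, axis=0)

    faces = []
    nxt = (np.arange(n_t) + 1) % n_t
    if closed_pole:
        ring0 = 1 + np.arange(n_t)
        for j in range(n_t):
            faces.append([0, ring0[j], ring0[nxt[j]]])
        base = 1
        n_rings = len(alphas) - 1
    else:
        base = 0
        n_rings = len(alphas)
    for i in range(n_rings - 1):
        r0 = base + i * n_t + np.arange(n_t)
        r1 = r0 + n_t
        for j in range(n_t):
            faces.append([r0[j], r1[j], r1[nxt[j]]])
            faces.append([r0[j], r1[nxt[j]], r0[nxt[j]]])
    return verts, np.asarray(faces, dtype=np.int64)


def _annulus(r_inner, r_outer, thetas):
    n_t = len(thetas)
    inner = np.stack([r_inner * np.cos(thetas), r_inner * np.sin(thetas),
                      np.zeros(n_t)], axis=-1)
    outer = np.stack([r_outer * np.cos(thetas), r_outer * np.sin(thetas),
                      np.zeros(n_t)], axis=-1)
    verts = np.concatenate([inner, outer], axis=0)
    nxt = (np.arange(n_t) + 1) % n_t
    faces = []
    for j in range(n_t):
        faces.append([j, n_t + j, n_t + nxt[j]])
        faces.append([j, n_t + nxt[j], nxt[j]])
    return verts, np.asarray(faces, dtype=np.int64)


def _assemble(parts):
    verts = []
    faces = []
    off = 0
    for v, f in parts:
        verts.append(v)
        faces.append(f + off)
        off += len(v)
    return np.concatenate(verts), np.concatenate(faces)


def _build_cup(spec: PhantomSpec):
    """Reconstructed cup shell in local coordinates (center at origin)."""
    L = spec.tessellation_level
    n_phi, n_theta = 6 * L, 24 * L
    alphas = np.pi / 2 * np.arange(n_phi + 1) / n_phi
    thetas = -np.pi + 2.0 * np.pi * np.arange(n_theta) / n_theta
    r_in = spec.cavity_radius
    r_out = spec.cavity_radius + spec.shell_thickness
    parts = [
        _spherical_patch(r_in, alphas, thetas, closed_pole=True),
        _spherical_patch(r_out, alphas, thetas, closed_pole=True),
        _annulus(r_in, r_out, thetas),
    ]
    if spec.detached_band is not None:
        band = spec.detached_band
        a0, a1 = band["phi_range"]
        t0, t1 = band["theta_range"]
        n_a = max(2, int(np.ceil((a1 - a0) / (np.pi / 2 / n_phi))))
        n_b = max(2, int(np.ceil((t1 - t0) / (2 * np.pi / n_theta))))
        b_alphas = np.linspace(a0, a1, n_a + 1)
        b_thetas = np.linspace(t0, t1, n_b + 1)
        bv = []
        for a in b_alphas:
            bv.append(band["radius"] * _cup_direction(a, b_thetas))
        bv = np.concatenate(bv)
        bf = []
        w = n_b + 1
        for i in range(n_a):
            for j in range(n_b):
                k = i * w + j
                bf.append([k, k + w, k + w + 1])
                bf.append([k, k + w + 1, k + 1])
        parts.append((bv, np.asarray(bf, dtype=np.int64)))
    return _assemble(parts)


def _local_spherical(points):
    """(phi from -Z pole, theta azimuth) of local-coordinate points."""
    r = np.linalg.norm(points, axis=-1)
    r = np.where(r == 0, 1.0, r)
    phi = np.arccos(np.clip(-points[..., 2] / r, -1.0, 1.0))
    theta = np.arctan2(points[..., 1], points[..., 0])
    return phi, theta


def _in_theta_range(theta, lo, hi):
    """Membership in the azimuth interval [lo, hi), wrapping at +-pi."""
    t = np.mod(theta - lo, 2.0 * np.pi)
    return t < np.mod(hi - lo - 1e-15, 2.0 * np.pi) + 1e-15


def _apply_defects(spec: PhantomSpec, verts, faces):
    verts = verts.copy()
    faces = faces.copy()
    r_in = spec.cavity_radius
    for op in spec.defects:
        if op.kind == "erosion":
            p = op.params
            vphi, vtheta = _local_spherical(verts)
            radii = np.linalg.norm(verts, axis=1)
            on_inner = np.abs(radii - r_in) < 1e-9
            a0, a1 = p.get("phi_range", (0.0, np.pi / 2))
            window = (on_inner & (vphi >= a0 - 1e-12) & (vphi <= a1 + 1e-12)
                      & _in_theta_range(vtheta, *p.get("theta_range", (-np.pi, np.pi))))
            scale = (radii + p["depth"]) / np.where(radii == 0, 1.0, radii)
            verts[window] *= scale[window, None]
        else:
            cphi, ctheta = _local_spherical(verts[faces].mean(axis=1))
            if op.kind == "theta_wedge":
                drop = _in_theta_range(ctheta, op.params["theta_min"], op.params["theta_max"])
            else:  # cap_hole
                drop = cphi < op.params["phi_max"]
            faces = faces[~drop]
    return verts, faces


def make_phantom(spec: PhantomSpec):
    """Generate one phantom case.

    Returns
    -------
    deficient, reconstructed : TriangleMesh
    config : CaseConfig (exact rim circle, inner-surface point subset,
        axis-aligning landmarks)
    truth : dict with the exact center, radius, axes, rim plane and any
        analytic expectations recorded by the preset
    """
    verts, faces = _build_cup(spec)
    if spec.empty_deficient:
        dverts, dfaces = np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64)
    else:
        dverts, dfaces = _apply_defects(spec, verts, faces)
        if len(dfaces) == 0:
            raise PhantomError("defects removed the entire shell")

    center = np.asarray(spec.center, dtype=float)
    R = np.eye(3) if spec.rotation is None else np.asarray(spec.rotation, dtype=float)

    def place(points):
        return points @ R.T + center

    reconstructed = TriangleMesh.from_arrays(place(verts), faces)
    if spec.empty_deficient:
        deficient = TriangleMesh.empty()
    else:
        deficient = TriangleMesh.from_arrays(place(dverts), dfaces)

    # exact rim circle (inner radius, rim plane) and inner-surface subset
    t_rim = np.linspace(-np.pi, np.pi, 40, endpoint=False)
    rim = place(np.stack([spec.cavity_radius * np.cos(t_rim),
                          spec.cavity_radius * np.sin(t_rim),
                          np.zeros(40)], axis=-1))
    radii = np.linalg.norm(verts, axis=1)
    inner_idx = np.flatnonzero(np.abs(radii - spec.cavity_radius) < 1e-9)
    rng = np.random.default_rng(spec.seed)
    take = rng.choice(inner_idx, size=min(300, len(inner_idx)), replace=False)
    region = place(verts[np.sort(take)])

    # landmarks: mediolateral along local -Z (medial), anterior +X; the ASIS
    # ordering encodes the side so the frame construction lands on +X/+Y
    if spec.side == "right":
        asis_l, asis_r = np.array([0.0, 0.0, -80.0]), np.array([0.0, 0.0, -20.0])
    else:
        asis_l, asis_r = np.array([0.0, 0.0, -20.0]), np.array([0.0, 0.0, -80.0])
    pubis = np.array([30.0, 0.0, -50.0])
    landmarks = {"asis_left": place(asis_l), "asis_right": place(asis_r),
                 "pubis": place(pubis)}
    config = CaseConfig(rim_outline=rim, acetabular_region=region,
                        landmarks=landmarks, side=spec.side)

    n = R @ np.array([0.0, 0.0, 1.0])
    ap = R @ np.array([1.0, 0.0, 0.0])
    sup = R @ (np.array([0.0, 1.0, 0.0]) if spec.side == "right"
               else np.array([0.0, -1.0, 0.0]))
    truth = {
        "center": center,
        "radius": spec.cavity_radius,
        "n": n,
        "ap_axis": ap,
        "sup_axis": sup,
        "rim_plane": {"point": center, "normal": n},
        "spec": spec,
        "expected": {},
    }
    return deficient, reconstructed, config, truth


def truth_frame(truth: dict) -> AcetabularFrame:
    """Exact acetabular frame of a phantom, bypassing all fitting."""
    plane = RimPlane(point=np.asarray(truth["rim_plane"]["point"], float),
                     normal=np.asarray(truth["rim_plane"]["normal"], float))
    return AcetabularFrame(center=np.asarray(truth["center"], float),
                           n=np.asarray(truth["n"], float), rim_plane=plane,
                           ap_axis=np.asarray(truth["ap_axis"], float),
                           sup_axis=np.asarray(truth["sup_axis"], float),
                           side=truth["spec"].side)


def truth_sphere(truth: dict) -> SphereFit:
    return SphereFit(center=np.asarray(truth["center"], float),
                     radius=float(truth["radius"]), rms_residual=0.0)


def _preset_specs() -> dict:
    band = {"radius": 40.0, "phi_range": (0.6 * np.pi, 0.7 * np.pi),
            "theta_range": (np.deg2rad(-144.0), np.deg2rad(-72.0))}
    return {
        "identity": PhantomSpec(),
        # quarter-turn wedge; endpoints lie on mesh-column edges and midway
        # between default-grid meridians, where the fractional corner
        # weighting integrates the cut exactly
        "wedge25": PhantomSpec(defects=(
            DefectOp("theta_wedge", {"theta_min": np.pi / 4, "theta_max": 3 * np.pi / 4}),)),
        "perforation": PhantomSpec(defects=(
            DefectOp("cap_hole", {"phi_max": np.pi / 4}),)),
        "erosion3": PhantomSpec(defects=(
            DefectOp("erosion", {"depth": 3.0, "theta_range": (0.0, np.pi / 2),
                                 "phi_range": (np.pi / 8, 3 * np.pi / 8)}),)),
        "needlehead": PhantomSpec(detached_band=band),
        "combined": PhantomSpec(defects=(
            DefectOp("theta_wedge", {"theta_min": -3 * np.pi / 4, "theta_max": -np.pi / 4}),
            DefectOp("cap_hole", {"phi_max": np.pi / 8}),
            DefectOp("erosion", {"depth": 3.0, "theta_range": (0.0, np.pi / 2),
                                 "phi_range": (np.pi / 8, 3 * np.pi / 8)}),)),
        "totalloss": PhantomSpec(empty_deficient=True),
    }


#: the six shipped fixtures used for oracle-equivalence checks
FIXTURE_PRESETS = ("identity", "wedge25", "perforation", "erosion3",
                   "needlehead", "combined")
#: all presets (totalloss has an intentionally empty deficient mesh)
PRESETS = tuple(_preset_specs())

# analytic expectations per preset, in percent (None where no closed form)
_EXPECTED = {
    "identity": {"global": 0.0, "PostInf": 0.0, "Inf": 0.0, "AntInf": 0.0,
                 "AntSup": 0.0, "PostSup": 0.0, "Med": 0.0},
    # the wedge spans psi in [45, 135) deg: 27/72 of AntSup [0,72),
    # 63/72 of PostSup [72,144); the medial cap loses the same azimuth
    # fraction 90/360
    "wedge25": {"global": 25.0, "AntSup": 100.0 * 27.0 / 72.0,
                "PostSup": 100.0 * 63.0 / 72.0, "Med": 25.0,
                "PostInf": 0.0, "Inf": 0.0, "AntInf": 0.0},
    # the hole phi < pi/4 engulfs the whole medial cap (phi <= pi/6) and an
    # annulus of each sector; planar shares: global (pi/4)^2/(pi/2)^2 = 1/4,
    # per sector ((pi/4)^2 - (pi/6)^2) / ((pi/2)^2 - (pi/6)^2) = 15.625%
    "perforation": {"global": 25.0, "Med": 100.0, "PostInf": 15.625,
                    "Inf": 15.625, "AntInf": 15.625, "AntSup": 15.625,
                    "PostSup": 15.625},
    "erosion3": {"global": 0.0, "PostInf": 0.0, "Inf": 0.0, "AntInf": 0.0,
                 "AntSup": 0.0, "PostSup": 0.0, "Med": 0.0},
    "needlehead": {"global": 0.0, "PostInf": 0.0, "Inf": 0.0, "AntInf": 0.0,
                   "AntSup": 0.0, "PostSup": 0.0, "Med": 0.0},
    "combined": {},
    "totalloss": {"global": 100.0, "PostInf": 100.0, "Inf": 100.0, "AntInf": 100.0,
                  "AntSup": 100.0, "PostSup": 100.0, "Med": 100.0},
}


def preset_spec(name: str) -> PhantomSpec:
    specs = _preset_specs()
    if name not in specs:
        raise PhantomError(f"unknown preset {name!r}; choose from {sorted(specs)}")
    return specs[name]


def make_preset(name: str):
    """Generate a named preset; truth['expected'] carries the analytic ratios."""
    deficient, reconstructed, config, truth = make_phantom(preset_spec(name))
    truth["expected"] = dict(_EXPECTED.get(name, {}))
    truth["preset"] = name
    return deficient, reconstructed, config, truth


def write_preset(name: str, outdir) -> dict:
    """Write deficient.stl, reconstructed.stl, case.json, truth.json."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    deficient, reconstructed, config, truth = make_preset(name)
    write_mesh(reconstructed, outdir / "reconstructed.stl")
    write_mesh(deficient, outdir / "deficient.stl")
    write_case_config(config, outdir / "case.json")
    spec = truth["spec"]
    doc = {
        "preset": name,
        "center": truth["center"].tolist(),
        "radius": truth["radius"],
        "n": truth["n"].tolist(),
        "ap_axis": truth["ap_axis"].tolist(),
        "sup_axis": truth["sup_axis"].tolist(),
        "expected_ratios_pct": truth["expected"],
        "cavity_radius": spec.cavity_radius,
        "shell_thickness": spec.shell_thickness,
        "tessellation_level": spec.tessellation_level,
        "side": spec.side,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(doc, fh, indent=1)
    return {"outdir": outdir}


def oracle_ratio(spec_or_name, dense_n: int = 400) -> dict:
    """Ground-truth ratios by the standalone dense brute-force path.

    Accepts a PhantomSpec or a preset name; returns region name -> ratio
    in percent (key "global" for the overall ratio), computed with
    ``dense_n x dense_n`` directions, an exhaustive per-ray triangle loop
    and all-corner cell areas — sharing no code with the main pipeline.
    """
    from .oracle import brute_force_ratios

    if isinstance(spec_or_name, str):
        deficient, reconstructed, _, truth = make_preset(spec_or_name)
    else:
        deficient, reconstructed, _, truth = make_phantom(spec_or_name)
    return brute_force_ratios(deficient, reconstructed,
                              center=truth["center"], n=truth["n"],
                              ap=truth["ap_axis"], sup=truth["sup_axis"],
                              dense_n=dense_n)
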