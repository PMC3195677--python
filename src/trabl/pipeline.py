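"""End-to-end orchestration of one analysis case.

Reads the two meshes and the case configuration, fits the sphere and rim
plane, builds the anatomical frame and ray grid, casts the rays, unfolds
the grid, assigns regions and evaluates the ratios; optionally writes all
tabular outputs, images and a machine-readable run log.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as tio
from .frame import frame_from_case
from .grid import build_grid
from .projection import evaluate, project_to_plane
from .raycast import compute_deviation_map
from .regions import assign_regions
from .report import ColorScale, plot_radar, render_color_graph


def run_case_objects(deficient, reconstructed, config, n_phi: int = 100,
                     n_theta: int = 100, metric: str = "planar",
                     sector_offset_deg: float = 0.0):
    """Run the pipeline on in-memory objects.

    Returns
    -------
    result : TrABLResult
    state : dict with frame, sphere, grid, deviation, planar, labels
    """
    frame, sphere = frame_from_case(reconstructed, config)
    grid = build_grid(frame, n_phi=n_phi, n_theta=n_theta)
    deviation = compute_deviation_map(grid, deficient, reconstructed)
    planar = project_to_plane(grid)
    labels = assign_regions(grid, sector_offset_deg=sector_offset_deg)
    result = evaluate(deviation, planar, labels, metric=metric, phi=grid.phi)
    result.metadata["sphere_fit"] = {
        "center": np.asarray(sphere.center).tolist(),
        "radius": sphere.radius,
        "rms_residual": sphere.rms_residual,
    }
    result.metadata["frame"] = {
        "n": frame.n.tolist(),
        "ap_axis": frame.ap_axis.tolist(),
        "sup_axis": frame.sup_axis.tolist(),
        "side": frame.side,
    }
    result.metadata["warnings"].extend(frame.warnings)
    state = {"frame": frame, "sphere": sphere, "grid": grid,
             "deviation": deviation, "planar": planar, "labels": labels}
    return result, state


def run_case(deficient_path, reconstructed_path, config_path, outdir=None,
             n_phi: int = 100, n_theta: int = 100, color_max: float = 10.0,
             metric: str = "planar", sector_offset_deg: float = 0.0,
             render: bool = True):
    """Run a full case from files; write outputs when *outdir* is given."""
    reconstructed = tio.read_mesh(reconstructed_path)
    deficient = tio.read_mesh(deficient_path)
    config = tio.read_case_config(config_path, reconstructed=reconstructed)
    result, state = run_case_objects(deficient, reconstructed, config,
                                     n_phi=n_phi, n_theta=n_theta, metric=metric,
                                     sector_offset_deg=sector_offset_deg)
    artifacts = {}
    if outdir is not None:
        outdir = Path(outdir)
        artifacts = tio.write_outputs(result, state["deviation"], state["grid"],
                                      state["planar"], outdir)
        log = {
            "inputs": {"deficient": str(deficient_path),
                       "reconstructed": str(reconstructed_path),
                       "config": str(config_path)},
            "grid": {"n_phi": n_phi, "n_theta": n_theta},
            "metric": metric,
            "color_range_mm": [0.0, color_max],
            "sphere_fit": result.metadata["sphere_fit"],
            "frame": result.metadata["frame"],
            "A_rec": result.A_rec,
            "A_def": result.A_def,
            "ratio_pct": result.ratio,
            "per_region_pct": {k: v.ratio for k, v in result.per_region.items()},
            "warnings": result.metadata["warnings"],
        }
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1)
        artifacts["run_log"] = outdir / "run_log.json"
        if render:
            scale = ColorScale(d_max=color_max)
            graph = render_color_graph(state["planar"], state["deviation"],
                                       state["labels"], scale)
            graph.save(outdir / "color_graph.png")
            artifacts["color_graph"] = outdir / "color_graph.png"
            fig = plot_radar(result)
            fig.savefig(outdir / "radar.png", dpi=150)
            import matplotlib.pyplot as plt
            plt.close(fig)
            artifacts["radar"] = outdir / "radar.png"
    return result, artifacts
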