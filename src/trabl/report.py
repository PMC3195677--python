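"""Rendering and cohort summaries.

The color graph shows the planar azimuthal map: grey where only the
reconstructed bone is intersected (total radial loss — no bony support in
that direction), a green-to-dark-red ramp over the Euclidean distance
deviation where the deficient bone is present (0 mm green, clamped at
10 mm dark red by default), and the base blue where deficient bone is hit
beyond the reconstructed outline. Overlay circles mark the arcs phi = pi/2
and phi = pi and the medial region; radial lines mark the five sector
boundaries.

Cohort summaries tabulate per-specimen and per-region extremes and
threshold-exceedance counts (strict >) over a table of per-region ratios.
A reference cohort of twelve highly deficient hemipelves (eleven Paprosky
type IIIB, one type IIc) ships with the package for the summary stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap, to_rgba

from .projection import PlanarMap, TrABLResult, corner_fractions
from .raycast import DeviationMap
from .regions import SECTOR_INTERVALS, SECTOR_ORDER, RegionLabels

REGION_COLUMNS = ("PostInf", "Inf", "AntInf", "AntSup", "PostSup", "Med")

_RAMP = LinearSegmentedColormap.from_list(
    "bone_loss", ["#00a000", "#ffff00", "#ff8000", "#8b0000"])


@dataclass(frozen=True)
class ColorScale:
    """Distance-to-color mapping for the deviation surface."""

    d_min: float = 0.0
    d_max: float = 10.0
    no_intersection_color: str = "#b0b0b0"
    reconstructed_only_color: str = "#b0b0b0"
    deficient_base_color: str = "#3050c8"

    def __post_init__(self):
        if not self.d_min < self.d_max:
            raise ValueError("color scale needs d_min < d_max")

    def rgba(self, distance):
        """Color of a finite distance; values >= d_max clamp to dark red."""
        d = np.clip((np.asarray(distance, dtype=float) - self.d_min)
                    / (self.d_max - self.d_min), 0.0, 1.0)
        return _RAMP(d)


@dataclass
class RenderedGraph:
    """A rendered color graph: the per-cell RGBA array (the testable pixel
    content) plus the matplotlib figure with overlays."""

    cell_colors: np.ndarray
    figure: object

    def save(self, path, dpi=150):
        self.figure.savefig(path, dpi=dpi, facecolor="white")
        plt.close(self.figure)

    def pixels(self) -> np.ndarray:
        self.figure.canvas.draw()
        return np.asarray(self.figure.canvas.buffer_rgba()).copy()


def render_color_graph(planar: PlanarMap, deviation: DeviationMap,
                       labels: RegionLabels | None = None,
                       scale: ColorScale | None = None,
                       overlays: bool = True) -> RenderedGraph:
    """Render the planar deviation map.

    Cell categories (by majority of the four corners):
    deficient+reconstructed hit -> ramp color at the mean corner deviation;
    reconstructed only -> grey (no radial bony support);
    deficient only -> base blue (bone beyond the reconstructed outline).
    """
    scale = scale or ColorScale()
    finite = np.isfinite(deviation.distance)
    w_pair = corner_fractions(deviation.hit_rec & deviation.hit_def & finite)
    w_rec = corner_fractions(deviation.hit_rec)
    w_def = corner_fractions(deviation.hit_def)

    # mean finite corner distance = sum(finite distances)/count(finite corners)
    sums = 4.0 * corner_fractions(np.where(finite, deviation.distance, 0.0))
    counts = 4.0 * corner_fractions(finite)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dist = np.where(counts > 0, sums / np.maximum(counts, 1e-12), 0.0)

    nphi_c, ntheta = w_rec.shape
    colors = np.ones((nphi_c, ntheta, 4))
    colors[..., 3] = 0.0  # background transparent
    rec_only = (w_rec >= 0.5) & (w_pair < 0.5)
    colors[rec_only] = to_rgba(scale.reconstructed_only_color)
    def_only = (w_def >= 0.5) & (w_rec < 0.5)
    colors[def_only] = to_rgba(scale.deficient_base_color)
    pair = w_pair >= 0.5
    colors[pair] = scale.rgba(mean_dist[pair])

    fig, ax = plt.subplots(figsize=(6, 6))
    # corner grids, azimuth wrapped closed for drawing
    x = np.concatenate([planar.x, planar.x[:, :1]], axis=1)
    y = np.concatenate([planar.y, planar.y[:, :1]], axis=1)
    ax.pcolormesh(x, y, colors, shading="flat")
    if overlays:
        t = np.linspace(0, 2 * np.pi, 361)
        ax.plot(np.pi / 2 * np.cos(t), np.pi / 2 * np.sin(t), "k-", lw=1.0)
        ax.plot(np.pi * np.cos(t), np.pi * np.sin(t), "-", color="green", lw=1.0)
        ax.plot(np.pi / 6 * np.cos(t), np.pi / 6 * np.sin(t), "-", color="gold", lw=1.0)
        for lo, _ in SECTOR_INTERVALS.values():
            a = np.deg2rad(lo)
            ax.plot([np.pi / 6 * np.cos(a), np.pi * np.cos(a)],
                    [np.pi / 6 * np.sin(a), np.pi * np.sin(a)], "k-", lw=0.6)
    ax.set_aspect("equal")
    ax.set_xlim(-np.pi * 1.05, np.pi * 1.05)
    ax.set_ylim(-np.pi * 1.05, np.pi * 1.05)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return RenderedGraph(cell_colors=colors, figure=fig)


def radar_data(result: TrABLResult):
    """Five sector ratios in fixed order plus the separate medial value."""
    sectors = [(name, result.per_region[name].ratio) for name in SECTOR_ORDER]
    return sectors, result.per_region["Med"].ratio


def plot_radar(result: TrABLResult, title: str = ""):
    """Radar plot of the five sector ratios; the medial ratio is shown as a
    separate bar (it has no angular direction)."""
    sectors, med = radar_data(result)
    names = [s[0] for s in sectors]
    vals = [0.0 if s[1] is None else s[1] for s in sectors]
    ang = np.deg2rad([np.mean(SECTOR_INTERVALS[n]) for n in names])
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(121, projection="polar")
    order = np.argsort(ang)
    a = np.append(ang[order], ang[order][0])
    v = np.append(np.array(vals)[order], np.array(vals)[order][0])
    ax.plot(a, v, "b-o")
    ax.fill(a, v, alpha=0.2)
    ax.set_xticks(ang)
    ax.set_xticklabels(names)
    ax.set_ylim(0, 100)
    ax.set_title(title or "sector ratios (%)", fontsize=9)
    axb = fig.add_subplot(122)
    axb.bar(["Med"], [0.0 if med is None else med], color="tab:gray")
    axb.set_ylim(0, 100)
    axb.set_title("medial ratio (%)", fontsize=9)
    fig.tight_layout()
    return fig


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort ratio table (specimen, age, sex, type, six regions)."""
    df = pd.read_csv(path)
    missing = [c for c in ("specimen",) + REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    block = df[list(REGION_COLUMNS)]
    if not all(np.issubdtype(t, np.number) for t in block.dtypes):
        raise ValueError("cohort ratio columns must be numeric")
    if block.isna().any().any():
        raise ValueError("cohort ratio columns contain missing values")
    return df


def load_reference_cohort() -> pd.DataFrame:
    """The packaged twelve-specimen reference cohort."""
    with resources.files("trabl.data").joinpath("reference_cohort.csv").open() as fh:
        return load_cohort(fh)


@dataclass
class CohortSummary:
    """Derived cohort statistics at the given thresholds (strict >)."""

    per_specimen_min: pd.Series
    per_specimen_max: pd.Series
    per_region_min: pd.Series
    per_region_max: pd.Series
    regions_over: pd.DataFrame      # specimen x threshold -> #regions > thr
    specimens_over: pd.DataFrame    # region x threshold -> #specimens > thr
    thresholds: tuple = (15.0, 25.0, 50.0)

    def specimens_with_at_least(self, threshold: float, k: int) -> int:
        """Number of specimens with >= k regions strictly above *threshold*."""
        return int((self.regions_over[threshold] >= k).sum())


def summarize_cohort(table: pd.DataFrame, thresholds=(15.0, 25.0, 50.0)) -> CohortSummary:
    """Per-specimen and per-region extremes and exceedance counts."""
    if len(table) < 1:
        raise ValueError("cohort table must have at least one row")
    block = table[list(REGION_COLUMNS)].astype(float)
    block.index = table["specimen"]
    thresholds = tuple(float(t) for t in thresholds)
    regions_over = pd.DataFrame(
        {t: (block > t).sum(axis=1) for t in thresholds})
    specimens_over = pd.DataFrame(
        {t: (block > t).sum(axis=0) for t in thresholds})
    return CohortSummary(
        per_specimen_min=block.min(axis=1),
        per_specimen_max=block.max(axis=1),
        per_region_min=block.min(axis=0),
        per_region_max=block.max(axis=0),
        regions_over=regions_over,
        specimens_over=specimens_over,
        thresholds=thresholds,
    )


def write_summary(summary: CohortSummary, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    spec_tbl = pd.DataFrame({"min": summary.per_specimen_min,
                             "max": summary.per_specimen_max})
    spec_tbl = spec_tbl.join(summary.regions_over.rename(
        columns={t: f"regions_over_{t:g}" for t in summary.thresholds}))
    paths["per_specimen"] = outdir / "summary_per_specimen.csv"
    spec_tbl.to_csv(paths["per_specimen"])
    reg_tbl = pd.DataFrame({"min": summary.per_region_min,
                            "max": summary.per_region_max})
    reg_tbl = reg_tbl.join(summary.specimens_over.rename(
        columns={t: f"specimens_over_{t:g}" for t in summary.thresholds}))
    paths["per_region"] = outdir / "summary_per_region.csv"
    reg_tbl.to_csv(paths["per_region"])
    return paths
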