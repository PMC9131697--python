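"""Kernel-density tissue maps, cortical depth profiles, and per-area
occurrences.

Density maps are fixed-bandwidth Gaussian KDEs evaluated on a regular grid
over a region polygon (units cells/um^2 before normalization) and masked
outside; a section is normalized by the single maximum over all types and
grid nodes so the brightest node is exactly 1.  Depth profiles project cell
centroids onto an oriented pial-to-white-matter axis, smooth the resulting
normalized depths with a 1-D Gaussian kernel whose integral preserves cell
counts, and integrate occupancy between fractional layer boundaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .regions import LAYER_NAMES, RegionAnnotation

DEFAULT_BANDWIDTH_UM = 100.0
DEFAULT_GRID_SPACING_UM = 20.0
DEFAULT_DEPTH_BANDWIDTH = 0.05  # fraction of cortical depth


@dataclass
class KDELayer:
    """One type's density raster: grid axes, values, and in-polygon mask."""

    x: np.ndarray           # grid-node x (um)
    y: np.ndarray           # grid-node y (um)
    values: np.ndarray      # (len(y), len(x)), 0 outside the polygon
    mask: np.ndarray        # True where the node is inside the polygon
    bandwidth: float
    n_cells: int

    def integral(self) -> float:
        """Mass inside the polygon by the trapezoid-free Riemann sum."""
        dx = float(np.mean(np.diff(self.x))) if len(self.x) > 1 else 1.0
        dy = float(np.mean(np.diff(self.y))) if len(self.y) > 1 else 1.0
        return float(self.values.sum() * dx * dy)


def kde_map(points: np.ndarray, polygon: Polygon,
            bandwidth: float = DEFAULT_BANDWIDTH_UM,
            grid_spacing: float = DEFAULT_GRID_SPACING_UM,
            grid: tuple[np.ndarray, np.ndarray] | None = None,
            edge_correction: bool = True) -> KDELayer:
    """Gaussian-kernel density of one cell population over a polygon.

    ``points`` is (n, 2) in um.  Values are sums of unit-mass isotropic
    Gaussians (per um^2), so the map integrates to about the cell count;
    nodes outside the polygon are masked to zero.  Zero cells yield an
    all-zero layer with a warning.

    With ``edge_correction`` (default) each node is divided by the fraction
    of a kernel's mass that falls inside the polygon at that node, the
    uniform boundary correction of spatial statistics: without it a
    homogeneous population looks artifactually dim along region borders,
    which would distort per-section-normalized maps.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if grid is None:
        minx, miny, maxx, maxy = polygon.bounds
        gx = np.arange(minx, maxx + grid_spacing / 2, grid_spacing)
        gy = np.arange(miny, maxy + grid_spacing / 2, grid_spacing)
    else:
        gx, gy = (np.asarray(g, dtype=float) for g in grid)
    xx, yy = np.meshgrid(gx, gy)
    nodes = shapely.points(np.column_stack([xx.ravel(), yy.ravel()]))
    mask = shapely.covers(polygon, nodes).reshape(len(gy), len(gx))

    if len(pts) == 0:
        warnings.warn("no cells: density layer is all zero")
        return KDELayer(gx, gy, np.zeros((len(gy), len(gx))), mask, bandwidth, 0)

    # separable kernel: values = Gy^T Gx / (2 pi h^2)
    h2 = bandwidth ** 2
    gauss_x = np.exp(-0.5 * (gx[None, :] - pts[:, 0, None]) ** 2 / h2)
    gauss_y = np.exp(-0.5 * (gy[None, :] - pts[:, 1, None]) ** 2 / h2)
    values = (gauss_y.T @ gauss_x) / (2.0 * np.pi * h2)
    if edge_correction:
        from scipy.ndimage import gaussian_filter
        spacing = (float(np.mean(np.diff(gx))) if len(gx) > 1 else 1.0,
                   float(np.mean(np.diff(gy))) if len(gy) > 1 else 1.0)
        inside_mass = gaussian_filter(mask.astype(float),
                                      sigma=(bandwidth / spacing[1],
                                             bandwidth / spacing[0]),
                                      mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(inside_mass > 0.05, values / inside_mass, values)
    values = np.where(mask, values, 0.0)
    return KDELayer(gx, gy, values, mask, bandwidth, len(pts))


def normalize_section(layers: Mapping[str, KDELayer]) -> dict[str, KDELayer]:
    """Scale all layers by the single maximum over types and grid nodes.

    After normalization the global maximum is exactly 1 (the brightest node
    of the densest type); relative brightness between types is preserved.
    For the spinal-cord display mode, call once per compartment so GM and
    WM are each normalized by their own across-type maximum.
    """
    peak = max(float(layer.values.max()) for layer in layers.values())
    if peak <= 0:
        raise ValueError("all density layers are zero; nothing to normalize")
    return {
        t: KDELayer(layer.x, layer.y, layer.values / peak, layer.mask,
                    layer.bandwidth, layer.n_cells)
        for t, layer in layers.items()
    }


def section_density_maps(called: pd.DataFrame, polygon: Polygon,
                         types: Sequence[str],
                         bandwidth: float = DEFAULT_BANDWIDTH_UM,
                         grid_spacing: float = DEFAULT_GRID_SPACING_UM,
                         normalize: bool = True) -> dict[str, KDELayer]:
    """Per-type KDE layers on one shared grid, optionally section-normalized."""
    minx, miny, maxx, maxy = polygon.bounds
    gx = np.arange(minx, maxx + grid_spacing / 2, grid_spacing)
    gy = np.arange(miny, maxy + grid_spacing / 2, grid_spacing)
    layers = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty types are fine section-wide
        for t in types:
            sub = called[called["called_type"] == t]
            layers[t] = kde_map(sub[["x_um", "y_um"]].to_numpy(), polygon,
                                bandwidth, grid_spacing, grid=(gx, gy))
    return normalize_section(layers) if normalize else layers


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Smoothed occurrence along normalized cortical depth (0 = pial surface).

    ``profiles[t]`` integrates to the number of type-t cells (up to the
    kernel mass smoothed past the [0, 1] boundary).
    """

    grid: np.ndarray
    profiles: dict[str, np.ndarray]
    depths: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    layer_breaks: tuple[float, ...] = ()
    bandwidth: float = DEFAULT_DEPTH_BANDWIDTH
    n_clipped: int = 0

    def layer_occupancy(self) -> pd.DataFrame:
        """Integral of each type's profile between consecutive layer breaks."""
        edges = np.concatenate([[0.0], np.asarray(self.layer_breaks), [1.0]])
        names = (list(LAYER_NAMES) if len(self.layer_breaks) == len(LAYER_NAMES) - 1
                 else [f"L{i + 1}" for i in range(len(edges) - 1)])
        rows = {}
        for t, prof in self.profiles.items():
            occ = []
            for lo, hi in zip(edges[:-1], edges[1:]):
                sel = (self.grid >= lo) & (self.grid <= hi)
                occ.append(float(np.trapezoid(prof[sel], self.grid[sel])))
            rows[t] = occ
        return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def project_depth(xy: np.ndarray,
                  depth_axis: tuple[tuple[float, float], tuple[float, float]]
                  ) -> np.ndarray:
    """Scalar projection onto the pial-to-white-matter axis, scaled to [0, 1]."""
    pial = np.asarray(depth_axis[0], dtype=float)
    deep = np.asarray(depth_axis[1], dtype=float)
    axis = deep - pial
    length2 = float(axis @ axis)
    if length2 <= 0:
        raise ValueError("depth_axis endpoints coincide")
    return ((np.asarray(xy, dtype=float) - pial) @ axis) / length2


def depth_profile(called: pd.DataFrame,
                  depth_axis: tuple[tuple[float, float], tuple[float, float]],
                  layer_breaks: Sequence[float] = (),
                  bandwidth: float = DEFAULT_DEPTH_BANDWIDTH,
                  types: Sequence[str] | None = None,
                  grid_n: int = 201) -> DepthProfile:
    """Per-type smoothed occurrence along normalized cortical depth.

    Each cell's depth is its scalar projection onto ``depth_axis`` (0 at the
    pial endpoint, 1 at the white-matter endpoint); projections outside
    [0, 1] are clipped and counted, with a warning when they exceed 5% of
    cells.  Occurrence is a Gaussian kernel sum (bandwidth as a fraction of
    the cortical depth) whose integral equals the cell count.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    raw = project_depth(called[["x_um", "y_um"]].to_numpy(), depth_axis)
    n_clipped = int(np.sum((raw < 0) | (raw > 1)))
    if len(raw) and n_clipped > 0.05 * len(raw):
        warnings.warn(f"{n_clipped}/{len(raw)} cells project outside [0, 1] "
                      "and were clipped; check the depth axis")
    depth = np.clip(raw, 0.0, 1.0)
    grid = np.linspace(0.0, 1.0, grid_n)
    if types is None:
        types = sorted(called["called_type"].unique())
    profiles: dict[str, np.ndarray] = {}
    depths: dict[str, np.ndarray] = {}
    for t in types:
        d = depth[(called["called_type"] == t).to_numpy()]
        depths[t] = d
        if len(d) == 0:
            profiles[t] = np.zeros_like(grid)
            continue
        z = (grid[None, :] - d[:, None]) / bandwidth
        profiles[t] = np.exp(-0.5 * z ** 2).sum(axis=0) / (bandwidth * np.sqrt(2 * np.pi))
    return DepthProfile(grid, profiles, depths, tuple(layer_breaks),
                        bandwidth, n_clipped)


def mean_depth_profiles(sections: Sequence[DepthProfile],
                        normalize: bool = False
                        ) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Across-section mean and SEM of depth profiles (shared grid required).

    ``normalize=True`` rescales each section's profile to unit integral
    before averaging, removing per-section cell-count differences.
    """
    grid = sections[0].grid
    types = list(sections[0].profiles)
    stacked = {t: [] for t in types}
    for sec in sections:
        if not np.array_equal(sec.grid, grid):
            raise ValueError("sections must share the same depth grid")
        for t in types:
            prof = sec.profiles[t]
            if normalize:
                total = np.trapezoid(prof, grid)
                prof = prof / total if total > 0 else prof
            stacked[t].append(prof)
    mean = pd.DataFrame({t: np.mean(stacked[t], axis=0) for t in types})
    sem = pd.DataFrame({t: np.std(stacked[t], axis=0, ddof=1) / np.sqrt(len(sections))
                        if len(sections) > 1 else np.zeros_like(grid)
                        for t in types})
    return grid, mean, sem


def area_occurrence(called: pd.DataFrame, areas: Mapping[str, Polygon],
                    types: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-area relative occurrence of each type (% of cells in the area).

    Cells are assigned to the first area polygon containing them (areas are
    expected to be disjoint); each area's counts are normalized by its own
    pan-marker-positive total so areas of different size are comparable.
    Empty areas yield NaN rows with a warning.
    """
    annot = RegionAnnotation(regions=dict(areas),
                             compartment_of={n: "GM" for n in areas})
    member = annot.locate(called["x_um"].to_numpy(), called["y_um"].to_numpy())
    if types is None:
        types = sorted(called["called_type"].unique())
    out = pd.DataFrame(np.nan, index=list(areas), columns=list(types))
    empty = []
    for name in areas:
        sub = called.loc[member == name, "called_type"]
        if len(sub) == 0:
            empty.append(name)
            continue
        counts = sub.value_counts().reindex(types, fill_value=0)
        out.loc[name] = 100.0 * counts / counts.sum()
    if empty:
        warnings.warn(f"areas with no cells: {empty}")
    return out
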