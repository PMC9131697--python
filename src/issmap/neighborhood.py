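"""Spatial neighbor graphs and permutation-based neighborhood enrichment.

Cells are nodes; edges come from the Delaunay triangulation (dual of the
Voronoi tessellation), which provably contains every node's true nearest
neighbor, so nearest neighbors and their Euclidean distances are read off
the graph.  Neighborhood preference is tested against a null built by
permuting cell-type labels over the fixed positions: the graph and the
label multiset are preserved exactly, only the label-to-position map is
randomized.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import voronoi_diagram

MIN_PERMUTATIONS = 100


@dataclass
class NeighborGraph:
    """Delaunay adjacency plus per-node nearest neighbors.

    ``edges`` is (m, 2) with i < j, symmetric by construction; ``nn_index``
    / ``nn_dist`` give each node's closest neighbor and its Euclidean
    distance in um.  If the triangulation is unavailable (< 3 nodes or
    degenerate geometry) ``triangulated`` is False and nearest neighbors
    come from brute force.
    """

    cell_ids: np.ndarray
    points: np.ndarray
    edges: np.ndarray
    nn_index: np.ndarray
    nn_dist: np.ndarray
    triangulated: bool
    voronoi_cells: dict[int, Polygon] | None = None

    @property
    def n(self) -> int:
        return len(self.points)

    def neighbor_lists(self) -> list[np.ndarray]:
        nbr: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            nbr[i].append(j)
            nbr[j].append(i)
        return [np.asarray(v, dtype=int) for v in nbr]


def _brute_force_nn(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    idx = d.argmin(axis=1)
    return idx, d[np.arange(len(points)), idx]


def _clipped_voronoi(points: np.ndarray, cell_ids: np.ndarray,
                     clip: Polygon) -> dict[int, Polygon]:
    cells = voronoi_diagram(MultiPoint(points.tolist()), envelope=clip)
    pts = shapely.points(points)
    out: dict[int, Polygon] = {}
    for poly in cells.geoms:
        inside = shapely.covers(poly, pts)
        for i in np.flatnonzero(inside):
            if int(cell_ids[i]) not in out:
                out[int(cell_ids[i])] = poly.intersection(clip)
    return out


def build_graph(cells: pd.DataFrame, clip: Polygon | None = None,
                compute_voronoi: bool = False) -> NeighborGraph:
    """Delaunay graph over cell centroids with nearest-neighbor annotation.

    ``cells`` needs columns cell_id, x_um, y_um.  With fewer than three
    nodes, or all nodes collinear, the triangulation is flagged unavailable
    and nearest neighbors fall back to an all-pairs search.  With
    ``compute_voronoi`` the Voronoi cell of each node is clipped to
    ``clip`` (required then), truncating unbounded cells.
    """
    points = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    cell_ids = cells["cell_id"].to_numpy()
    n = len(points)
    if n < 2:
        raise ValueError("need >= 2 cells for a neighbor graph")

    triangulated = True
    edges = np.empty((0, 2), dtype=int)
    try:
        if n < 3:
            raise ValueError("too few points")
        tri = Delaunay(points)
        indptr, indices = tri.vertex_neighbor_vertices
        pairs = [(i, j) for i in range(n) for j in indices[indptr[i]:indptr[i + 1]]
                 if i < j]
        edges = np.asarray(pairs, dtype=int)
        nn_index = np.empty(n, dtype=int)
        nn_dist = np.empty(n, dtype=float)
        for i in range(n):
            nbrs = indices[indptr[i]:indptr[i + 1]]
            d = np.hypot(*(points[nbrs] - points[i]).T)
            k = d.argmin()
            nn_index[i] = nbrs[k]
            nn_dist[i] = d[k]
    except Exception:  # QhullError on degenerate input, or n < 3
        triangulated = False
        warnings.warn("Delaunay triangulation unavailable (degenerate or too "
                      "few points); nearest neighbors from brute force")
        nn_index, nn_dist = _brute_force_nn(points)

    voronoi_cells = None
    if compute_voronoi and triangulated:
        if clip is None:
            raise ValueError("compute_voronoi requires a clip polygon")
        voronoi_cells = _clipped_voronoi(points, cell_ids, clip)

    return NeighborGraph(cell_ids, points, edges, nn_index, nn_dist,
                         triangulated, voronoi_cells)


def _label_codes(labels: Sequence[str],
                 types: Sequence[str] | None) -> tuple[np.ndarray, list[str]]:
    labels = np.asarray(labels)
    type_list = list(types) if types is not None else sorted(set(labels.tolist()))
    lut = {t: k for k, t in enumerate(type_list)}
    unknown = set(labels.tolist()) - set(type_list)
    if unknown:
        raise ValueError(f"labels outside the type list: {sorted(unknown)}")
    return np.array([lut[v] for v in labels], dtype=int), type_list


def nn_composition(graph: NeighborGraph, labels: Sequence[str],
                   types: Sequence[str] | None = None) -> pd.DataFrame:
    """Row-normalized nearest-neighbor type composition, in percent.

    Entry (a, b) is the percentage of type-a cells whose nearest neighbor
    is of type b; each defined row sums to 100.  Types without cells give
    NaN rows (flagged).
    """
    codes, type_list = _label_codes(labels, types)
    k = len(type_list)
    pair = codes * k + codes[graph.nn_index]
    counts = np.bincount(pair, minlength=k * k).reshape(k, k).astype(float)
    row_n = counts.sum(axis=1)
    out = np.full((k, k), np.nan)
    ok = row_n > 0
    out[ok] = 100.0 * counts[ok] / row_n[ok, None]
    if not ok.all():
        warnings.warn(f"types with no cells: {[type_list[i] for i in np.flatnonzero(~ok)]}")
    return pd.DataFrame(out, index=type_list, columns=type_list)


def nn_mean_distance(graph: NeighborGraph, labels: Sequence[str],
                     types: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean distance (um) from each type to its most prevalent NN type.

    For type a, the partner b* is the argmax of row a in the NN
    composition; ties go to the earlier type in panel order (flagged).
    Returns per type: the partner, the mean Euclidean NN distance over
    type-a cells whose nearest neighbor is of type b*, and the cell count
    entering the mean.
    """
    codes, type_list = _label_codes(labels, types)
    comp = nn_composition(graph, labels, type_list)
    rows = []
    for a, t in enumerate(type_list):
        row = comp.loc[t].to_numpy()
        if np.isnan(row).all():
            rows.append((t, None, np.nan, 0))
            continue
        best = float(np.nanmax(row))
        winners = np.flatnonzero(row == best)
        if len(winners) > 1:
            warnings.warn(f"tie for most prevalent neighbor of {t!r}; "
                          "taking the earlier panel type")
        b = int(winners[0])
        sel = (codes == a) & (codes[graph.nn_index] == b)
        rows.append((t, type_list[b], float(graph.nn_dist[sel].mean()),
                     int(sel.sum())))
    return pd.DataFrame(rows, columns=["type", "nn_type", "mean_distance_um",
                                       "n_cells"]).set_index("type")


def _pair_counts(codes: np.ndarray, nn: np.ndarray, k: int,
                 statistic: str, edges: np.ndarray) -> np.ndarray:
    if statistic == "nn_count":
        pair = codes * k + codes[nn]
        return np.bincount(pair, minlength=k * k).reshape(k, k)
    if statistic == "edge_count":
        a, b = codes[edges[:, 0]], codes[edges[:, 1]]
        counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
        return counts + counts.T  # symmetric ordered counts
    raise ValueError(f"unknown statistic {statistic!r}")


def enrichment_test(graph: NeighborGraph, labels: Sequence[str],
                    n_permutations: int = 1000, seed: int = 0,
                    statistic: str = "nn_count",
                    alternative: str = "greater",
                    types: Sequence[str] | None = None) -> pd.DataFrame:
    """Permutation test of neighborhood preference per ordered type pair.

    The observed statistic (nearest-neighbor pair counts by default, or
    symmetric Delaunay edge counts) is compared against ``n_permutations``
    label shuffles on the fixed graph.  z = (obs - null mean) / null sd;
    the empirical p uses the add-one correction
    ``p = (1 + #{null >= obs}) / (1 + n_permutations)`` for enrichment
    (one-sided by default; ``alternative='two-sided'`` doubles the smaller
    tail).  Pairs with zero null variance get NaN z but keep the empirical p.
    """
    if n_permutations < MIN_PERMUTATIONS:
        raise ValueError(f"n_permutations must be >= {MIN_PERMUTATIONS}")
    if statistic == "edge_count" and not graph.triangulated:
        raise ValueError("edge_count statistic requires a triangulated graph")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    codes, type_list = _label_codes(labels, types)
    k = len(type_list)
    rng = np.random.default_rng(seed)

    observed = _pair_counts(codes, graph.nn_index, k, statistic, graph.edges)
    null = np.empty((n_permutations, k, k), dtype=float)
    for p in range(n_permutations):
        perm = rng.permutation(codes)
        null[p] = _pair_counts(perm, graph.nn_index, k, statistic, graph.edges)

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - mean) / sd, np.nan)
    n_ge = (null >= observed[None]).sum(axis=0)
    p_greater = (1.0 + n_ge) / (1.0 + n_permutations)
    if alternative == "two-sided":
        n_le = (null <= observed[None]).sum(axis=0)
        p_less = (1.0 + n_le) / (1.0 + n_permutations)
        p_emp = np.minimum(1.0, 2.0 * np.minimum(p_greater, p_less))
    else:
        p_emp = p_greater

    rows = []
    for a in range(k):
        for b in range(k):
            rows.append((type_list[a], type_list[b], float(observed[a, b]),
                         float(mean[a, b]), float(sd[a, b]),
                         float(z[a, b]), float(p_emp[a, b])))
    out = pd.DataFrame(rows, columns=["type_a", "type_b", "observed",
                                      "null_mean", "null_sd", "z", "p"])
    out.attrs.update(n_permutations=n_permutations, seed=seed,
                     statistic=statistic, alternative=alternative)
    return out
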