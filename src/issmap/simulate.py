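"""Synthetic tissue generator with the statistical structure of decoded
in situ sequencing data.

Cells are placed by a homogeneous spatial Poisson process per region, typed
by region-dependent abundance fractions, and emit per-gene transcript counts
drawn from a Poisson (optionally negative-binomial) model whose mean follows
the reference profile of the cell's type scaled to a target transcripts-per-
cell.  Each transcript becomes a spot displaced isotropically (Gaussian)
from the cell centroid; background spots with uniform positions and uniform
gene identities are added on top.  Everything is reproducible from one seed.

Presets encode the study conditions per age: mean transcripts per cell of
13.4 (P10), 14.6 (P20) and 17.4 (P60), cortical vs callosal densities of
roughly 170-210 and 600-750 cells/mm^2, and age-appropriate type mixes
(precursor-rich early, MOL5/6-dominated in the adult).
"""
from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .profiles import ReferenceProfiles, make_reference_profiles
from .regions import RegionAnnotation, make_layout

BACKGROUND = 0  # parent cell id for noise spots


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator (units in the field names).

    ``cell_density`` is cells/mm^2, either one number or per region name.
    ``background_rate`` is noise spots per mm^2 of the layout bounding box;
    ``None`` targets 5% of the expected true spot count.  ``dispersion``
    switches per-gene counts from Poisson to negative binomial (gamma shape
    parameter; smaller = more overdispersed).
    """

    cell_density: float | Mapping[str, float] = 300.0
    mean_transcripts: float = 15.0
    spot_sigma: float = 4.0
    background_rate: float | None = None
    dispersion: float | None = None
    cell_area_median: float = 80.0
    cell_area_sigma: float = 0.5

    def density_for(self, region: str) -> float:
        if isinstance(self.cell_density, Mapping):
            return float(self.cell_density[region])
        return float(self.cell_density)


@dataclass
class GroundTruthTissue:
    """Simulated section: cells with known types, spots, and provenance.

    ``cells`` columns: cell_id, x_um, y_um, area_um2, region, true_type.
    ``spots`` columns: spot_id, gene, x_um, y_um, cell (0 = background).
    """

    cells: pd.DataFrame
    spots: pd.DataFrame
    abundance_spec: dict[str, dict[str, float]]
    params: SimulationParams
    seed: int
    layout: RegionAnnotation | None = None


def _validate_abundance_spec(spec: Mapping[str, Mapping[str, float]],
                             layout: RegionAnnotation,
                             type_ids: tuple[str, ...]) -> None:
    for region in layout.regions:
        if region not in spec:
            raise ValueError(f"abundance_spec missing region {region!r}")
        fr = spec[region]
        unknown = set(fr) - set(type_ids)
        if unknown:
            raise ValueError(f"abundance_spec for {region!r} has unknown types {unknown}")
        total = float(sum(fr.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"abundance fractions for {region!r} sum to {total}, not 1")
        if any(v < 0 for v in fr.values()):
            raise ValueError(f"abundance fractions for {region!r} must be >= 0")


def sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(64, int(1.5 * (n - filled) * (maxx - minx) * (maxy - miny)
                        / max(poly.area, 1e-12)))
        cand = np.column_stack([rng.uniform(minx, maxx, m),
                                rng.uniform(miny, maxy, m)])
        ok = shapely.covers(poly, shapely.points(cand))
        take = cand[ok][: n - filled]
        out[filled:filled + len(take)] = take
        filled += len(take)
    return out


def simulate_tissue(
    profiles: ReferenceProfiles,
    layout: RegionAnnotation,
    abundance_spec: Mapping[str, Mapping[str, float]],
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
) -> GroundTruthTissue:
    """Simulate one section.  Fully reproducible from ``seed``."""
    _validate_abundance_spec(abundance_spec, layout, profiles.type_ids)
    for region in layout.regions:
        if params.density_for(region) <= 0:
            raise ValueError(f"cell density for {region!r} must be > 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    q = profiles.normalized()  # per-type expression fractions

    # --- cells -------------------------------------------------------------
    rows = []
    for region, poly in layout.regions.items():
        lam = params.density_for(region) * poly.area / 1e6
        n = int(rng.poisson(lam))
        xy = sample_in_polygon(poly, n, rng)
        fr = np.array([abundance_spec[region].get(t, 0.0)
                       for t in profiles.type_ids])
        t_idx = rng.choice(profiles.n_types, size=n, p=fr)
        areas = params.cell_area_median * np.exp(
            rng.normal(0.0, params.cell_area_sigma, n))
        for i in range(n):
            rows.append((xy[i, 0], xy[i, 1], areas[i], region,
                         profiles.type_ids[t_idx[i]]))
    cells = pd.DataFrame(rows, columns=["x_um", "y_um", "area_um2",
                                        "region", "true_type"])
    cells.insert(0, "cell_id", np.arange(1, len(cells) + 1))

    # --- per-cell transcript counts ---------------------------------------
    n_cells = len(cells)
    type_index = {t: k for k, t in enumerate(profiles.type_ids)}
    t_of_cell = cells["true_type"].map(type_index).to_numpy()
    lam_mat = params.mean_transcripts * q[:, t_of_cell].T  # cells x genes
    if params.dispersion is None:
        counts = rng.poisson(lam_mat)
    else:
        r = float(params.dispersion)
        rate = rng.gamma(r, lam_mat / r)
        counts = rng.poisson(rate)

    # --- spots -------------------------------------------------------------
    total = int(counts.sum())
    cell_of_spot = np.repeat(cells["cell_id"].to_numpy(),
                             counts.sum(axis=1))
    gene_idx = np.concatenate(
        [np.repeat(np.arange(profiles.n_genes), counts[i])
         for i in range(n_cells)]) if n_cells else np.empty(0, dtype=int)
    cx = np.repeat(cells["x_um"].to_numpy(), counts.sum(axis=1))
    cy = np.repeat(cells["y_um"].to_numpy(), counts.sum(axis=1))
    sx = cx + rng.normal(0.0, params.spot_sigma, total)
    sy = cy + rng.normal(0.0, params.spot_sigma, total)

    minx, miny, maxx, maxy = layout.bounds()
    bbox_mm2 = (maxx - minx) * (maxy - miny) / 1e6
    if params.background_rate is None:
        n_bg = int(rng.poisson(0.05 * total))
    else:
        n_bg = int(rng.poisson(params.background_rate * bbox_mm2))
    bg_gene = rng.integers(0, profiles.n_genes, n_bg)
    bg_x = rng.uniform(minx, maxx, n_bg)
    bg_y = rng.uniform(miny, maxy, n_bg)

    gene_names = np.asarray(profiles.gene_ids, dtype=object)
    spots = pd.DataFrame({
        "gene": np.concatenate([gene_names[gene_idx], gene_names[bg_gene]]),
        "x_um": np.concatenate([sx, bg_x]),
        "y_um": np.concatenate([sy, bg_y]),
        "cell": np.concatenate([cell_of_spot,
                                np.full(n_bg, BACKGROUND, dtype=int)]),
    })
    spots.insert(0, "spot_id", np.arange(1, len(spots) + 1))

    return GroundTruthTissue(cells=cells, spots=spots,
                             abundance_spec={r: dict(f) for r, f in abundance_spec.items()},
                             params=params, seed=seed, layout=layout)


def shuffle_labels(tissue: GroundTruthTissue, seed: int = 0) -> GroundTruthTissue:
    """Permute ground-truth type labels across cells; positions untouched.

    This is the null configuration used by the permutation-based
    neighborhood test: the label multiset and all positional information are
    preserved exactly.
    """
    if len(tissue.cells) == 0:
        raise ValueError("tissue has no cells")
    rng = np.random.default_rng(seed)
    cells = tissue.cells.copy()
    perm = rng.permutation(len(cells))
    cells["true_type"] = cells["true_type"].to_numpy()[perm]
    return GroundTruthTissue(cells=cells, spots=tissue.spots.copy(),
                             abundance_spec=copy.deepcopy(tissue.abundance_spec),
                             params=tissue.params, seed=tissue.seed,
                             layout=tissue.layout)


# ---------------------------------------------------------------------------
# Presets: the per-age study conditions.
# ---------------------------------------------------------------------------

_BRAIN_SPECS: dict[str, dict[str, dict[str, float]]] = {
    "p10": {
        "CTX": {"OPC": .18, "COP": .12, "NFOL1": .14, "NFOL2": .06,
                "MFOL1": .10, "MFOL2": .12, "MOL1": .05, "MOL2": .03,
                "MOL3": .04, "MOL4": .03, "MOL5": .05, "MOL6": .03, "VLMC": .05},
        "CC": {"OPC": .16, "COP": .16, "NFOL1": .17, "NFOL2": .05,
               "MFOL1": .08, "MFOL2": .09, "MOL1": .07, "MOL2": .03,
               "MOL3": .03, "MOL4": .03, "MOL5": .04, "MOL6": .03, "VLMC": .06},
    },
    "p20": {
        "CTX": {"OPC": .14, "COP": .09, "NFOL1": .11, "NFOL2": .07,
                "MFOL1": .11, "MFOL2": .11, "MOL1": .06, "MOL2": .04,
                "MOL3": .04, "MOL4": .04, "MOL5": .10, "MOL6": .04, "VLMC": .05},
        "CC": {"OPC": .13, "COP": .12, "NFOL1": .12, "NFOL2": .05,
               "MFOL1": .09, "MFOL2": .08, "MOL1": .05, "MOL2": .04,
               "MOL3": .04, "MOL4": .03, "MOL5": .12, "MOL6": .04, "VLMC": .09},
    },
    "p60": {
        "CTX": {"OPC": .12, "COP": .04, "NFOL1": .03, "NFOL2": .03,
                "MFOL1": .05, "MFOL2": .04, "MOL1": .03, "MOL2": .10,
                "MOL3": .08, "MOL4": .03, "MOL5": .25, "MOL6": .15, "VLMC": .05},
        "CC": {"OPC": .10, "COP": .05, "NFOL1": .04, "NFOL2": .03,
               "MFOL1": .08, "MFOL2": .04, "MOL1": .02, "MOL2": .12,
               "MOL3": .08, "MOL4": .02, "MOL5": .30, "MOL6": .10, "VLMC": .02},
    },
}

_CORD_SPECS: dict[str, dict[str, dict[str, float]]] = {
    "p20_cord": {
        "GM": {"OPC": .16, "COP": .08, "NFOL1": .08, "NFOL2": .04,
               "MFOL1": .06, "MFOL2": .05, "MOL1": .10, "MOL2": .05,
               "MOL3": .03, "MOL4": .04, "MOL5": .14, "MOL6": .12, "VLMC": .05},
        "WM": {"OPC": .07, "COP": .07, "NFOL1": .05, "NFOL2": .03,
               "MFOL1": .07, "MFOL2": .05, "MOL1": .05, "MOL2": .16,
               "MOL3": .14, "MOL4": .04, "MOL5": .12, "MOL6": .09, "VLMC": .06},
    },
    "p60_cord": {
        "GM": {"OPC": .14, "COP": .07, "NFOL1": .05, "NFOL2": .03,
               "MFOL1": .04, "MFOL2": .04, "MOL1": .10, "MOL2": .05,
               "MOL3": .03, "MOL4": .04, "MOL5": .18, "MOL6": .18, "VLMC": .05},
        "WM": {"OPC": .06, "COP": .05, "NFOL1": .04, "NFOL2": .03,
               "MFOL1": .06, "MFOL2": .04, "MOL1": .04, "MOL2": .20,
               "MOL3": .15, "MOL4": .04, "MOL5": .14, "MOL6": .10, "VLMC": .05},
    },
}

_AGE_PARAMS: dict[str, tuple[float, dict[str, float]]] = {
    # mean transcripts per cell, density per region (cells/mm^2)
    "p10": (13.4, {"CTX": 207.2, "CC": 648.4}),
    "p20": (14.6, {"CTX": 193.5, "CC": 750.4}),
    "p60": (17.4, {"CTX": 170.1, "CC": 608.6}),
    "p20_cord": (14.6, {"GM": 350.0, "WM": 650.0}),
    "p60_cord": (17.4, {"GM": 350.0, "WM": 650.0}),
}

PRESETS = tuple(_AGE_PARAMS) + ("demo",)


def preset_tissue(name: str, seed: int = 0, scale: float | None = None,
                  profiles: ReferenceProfiles | None = None
                  ) -> tuple[GroundTruthTissue, ReferenceProfiles]:
    """Simulate one section under a named study condition.

    ``demo`` is a small brain section (scale 400 um) for smoke runs; the age
    presets (p10/p20/p60 brain, p20_cord/p60_cord spinal cord) use the
    per-age transcript yields, densities and abundance mixes.
    """
    if profiles is None:
        profiles = make_reference_profiles(seed=0)
    if name == "demo":
        layout = make_layout("brain_coronal", scale or 400.0)
        params = SimulationParams(cell_density={"CTX": 250.0, "CC": 700.0},
                                  mean_transcripts=15.0)
        spec = _BRAIN_SPECS["p60"]
    elif name in _BRAIN_SPECS:
        layout = make_layout("brain_coronal", scale or 1000.0)
        mean_tx, dens = _AGE_PARAMS[name]
        params = SimulationParams(cell_density=dens, mean_transcripts=mean_tx)
        spec = _BRAIN_SPECS[name]
    elif name in _CORD_SPECS:
        layout = make_layout("spinal_cord", scale or 600.0)
        mean_tx, dens = _AGE_PARAMS[name]
        params = SimulationParams(cell_density=dens, mean_transcripts=mean_tx)
        spec = _CORD_SPECS[name]
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    tissue = simulate_tissue(profiles, layout, spec, params, seed=seed)
    return tissue, profiles
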