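"""CSV/GeoJSON readers, writers, and input validation.

File contracts:

* spots:    ``spot_id,gene,x_um,y_um``
* cells:    ``cell_id,x_um,y_um,area_um2,region[,true_type]``
* called:   ``cell_id,x_um,y_um,region,called_type,max_probability,pan_count``
* profiles: matrix CSV, rows = genes (first column ``gene``), columns = types
* regions:  GeoJSON FeatureCollection of polygons with properties ``name``,
  ``compartment`` and optional ``layer_breaks`` / ``depth_axis``
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape

from .profiles import ReferenceProfiles
from .regions import RegionAnnotation

SPOT_COLUMNS = ["spot_id", "gene", "x_um", "y_um"]
CELL_COLUMNS = ["cell_id", "x_um", "y_um", "area_um2", "region"]
CALLED_COLUMNS = ["cell_id", "x_um", "y_um", "region", "called_type",
                  "max_probability", "pan_count"]


def write_spots(spots: pd.DataFrame, path: str | Path) -> None:
    spots[SPOT_COLUMNS].to_csv(path, index=False)


def read_spots(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cols = CELL_COLUMNS + (["true_type"] if "true_type" in cells.columns else [])
    cells[cols].to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_called(called: pd.DataFrame, path: str | Path) -> None:
    called[CALLED_COLUMNS].to_csv(path, index=False)


def read_called(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _check_columns(frame: pd.DataFrame, required: list[str], what: str,
                   issues: list[dict]) -> bool:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        issues.append({"file": what, "issue": "missing columns",
                       "detail": missing})
        return False
    return True


def validate_inputs(spots: str | Path | None = None,
                    cells: str | Path | None = None,
                    profiles: str | Path | None = None,
                    regions: str | Path | None = None) -> list[dict]:
    """Schema and consistency checks; returns a machine-readable issue list.

    Each issue is ``{"file": ..., "issue": ..., "detail": ...}``.  An empty
    list means the inputs are mutually consistent: coordinates finite, ids
    unique, spot genes inside the panel, polygons valid.
    """
    issues: list[dict] = []
    panel: set[str] | None = None

    if profiles is not None:
        try:
            prof = ReferenceProfiles.from_csv(profiles)
            panel = set(prof.gene_ids)
        except Exception as exc:  # malformed matrix / invariant breach
            issues.append({"file": str(profiles), "issue": "unreadable profiles",
                           "detail": str(exc)})

    if spots is not None:
        try:
            sp = pd.read_csv(spots)
        except Exception as exc:
            issues.append({"file": str(spots), "issue": "parse error",
                           "detail": str(exc)})
            sp = None
        if sp is not None and _check_columns(sp, SPOT_COLUMNS, str(spots), issues):
            coords = sp[["x_um", "y_um"]].to_numpy(dtype=float)
            if not np.isfinite(coords).all():
                issues.append({"file": str(spots), "issue": "non-finite coordinates",
                               "detail": int((~np.isfinite(coords)).any(axis=1).sum())})
            if panel is not None:
                bad = sp.loc[~sp["gene"].isin(panel), "gene"]
                if len(bad):
                    issues.append({"file": str(spots), "issue": "gene not in panel",
                                   "detail": {"count": int(len(bad)),
                                              "examples": sorted(set(bad))[:5]}})

    if cells is not None:
        try:
            ce = pd.read_csv(cells)
        except Exception as exc:
            issues.append({"file": str(cells), "issue": "parse error",
                           "detail": str(exc)})
            ce = None
        if ce is not None and _check_columns(ce, CELL_COLUMNS, str(cells), issues):
            if ce["cell_id"].duplicated().any():
                issues.append({"file": str(cells), "issue": "duplicate cell_id",
                               "detail": int(ce["cell_id"].duplicated().sum())})
            if (ce["area_um2"] <= 0).any():
                issues.append({"file": str(cells), "issue": "non-positive area",
                               "detail": int((ce["area_um2"] <= 0).sum())})

    if regions is not None:
        try:
            data = json.loads(Path(regions).read_text())
            for i, feat in enumerate(data.get("features", [])):
                name = feat.get("properties", {}).get("name", f"feature {i}")
                geom = shape(feat["geometry"])
                if not geom.is_valid:
                    issues.append({"file": str(regions), "issue": "invalid geometry",
                                   "detail": name})
            RegionAnnotation.from_geojson(regions)
        except Exception as exc:
            issues.append({"file": str(regions), "issue": "unreadable regions",
                           "detail": str(exc)})

    return issues
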