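"""Reference expression profiles for a targeted gene panel.

A panel couples an ordered list of gene symbols to an ordered list of cell
types through a matrix of mean expression per cell (genes x types), plus a
designated pan-lineage marker gene used to gate which segmented cells enter
the analysis (the role *Plp1* plays for the oligodendrocyte lineage).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The thirteen oligodendrocyte-lineage reference populations (precursors,
#: committed precursors, newly-formed / myelin-forming / mature oligodendrocytes,
#: and vascular-and-leptomeningeal cells).
OL_LINEAGE_TYPES: tuple[str, ...] = (
    "OPC", "COP", "NFOL1", "NFOL2", "MFOL1", "MFOL2",
    "MOL1", "MOL2", "MOL3", "MOL4", "MOL5", "MOL6", "VLMC",
)

DEFAULT_PAN_MARKER = "Plp1"


@dataclass(frozen=True)
class ReferenceProfiles:
    """Mean expression per gene and cell type, with a pan-lineage marker.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene symbols (panel order; ties elsewhere break on it).
    type_ids
        Ordered, unique cell-type names.
    mean_expr
        Non-negative matrix of shape ``(len(gene_ids), len(type_ids))``:
        mean transcript count per cell of each type.
    pan_marker
        Gene symbol expressed in every lineage type; must be in ``gene_ids``
        and have strictly positive mean in every type.
    """

    gene_ids: tuple[str, ...]
    type_ids: tuple[str, ...]
    mean_expr: np.ndarray
    pan_marker: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "type_ids", tuple(self.type_ids))
        expr = np.asarray(self.mean_expr, dtype=float)
        object.__setattr__(self, "mean_expr", expr)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.type_ids)) != len(self.type_ids):
            raise ValueError("type_ids must be unique")
        if expr.shape != (len(self.gene_ids), len(self.type_ids)):
            raise ValueError(
                f"mean_expr shape {expr.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.type_ids)} types)"
            )
        if not np.all(np.isfinite(expr)) or np.any(expr < 0):
            raise ValueError("mean_expr entries must be finite and >= 0")
        if not np.all((expr > 0).any(axis=0)):
            raise ValueError("every type needs >= 1 gene with positive mean")
        if self.pan_marker not in self.gene_ids:
            raise ValueError(f"pan_marker {self.pan_marker!r} not in gene_ids")
        if np.any(expr[self.gene_index(self.pan_marker)] <= 0):
            raise ValueError("pan_marker must have positive mean in every type")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_ids)

    def gene_index(self, gene: str) -> int:
        return self.gene_ids.index(gene)

    def normalized(self, pseudocount: float = 0.0) -> np.ndarray:
        """Per-type expression fractions ``(mean_expr + eps)`` column-normalized."""
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        q = self.mean_expr + pseudocount
        return q / q.sum(axis=0, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_expr, index=list(self.gene_ids),
                            columns=list(self.type_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, pan_marker: str) -> "ReferenceProfiles":
        return cls(tuple(frame.index), tuple(frame.columns),
                   frame.to_numpy(dtype=float), pan_marker)

    def to_csv(self, path: str | Path) -> None:
        # rows = genes, columns = types, first column = gene symbol
        frame = self.to_frame()
        frame.index.name = "gene"
        frame.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path,
                 pan_marker: str = DEFAULT_PAN_MARKER) -> "ReferenceProfiles":
        frame = pd.read_csv(path, index_col=0)
        return cls.from_frame(frame, pan_marker)


def _default_type_names(n_types: int) -> list[str]:
    if n_types == len(OL_LINEAGE_TYPES):
        return list(OL_LINEAGE_TYPES)
    return [f"T{i + 1:02d}" for i in range(n_types)]


def make_reference_profiles(
    n_types: int = 13,
    markers_per_type: int = 9,
    n_shared_genes: int = 6,
    marker_level: float = 3.0,
    off_level: float = 0.05,
    seed: int = 0,
    type_ids: Sequence[str] | None = None,
    pan_marker: str = DEFAULT_PAN_MARKER,
    pan_level: float | None = None,
) -> ReferenceProfiles:
    """Build a synthetic marker panel with the structure of a targeted assay.

    Each type gets ``markers_per_type`` dedicated genes elevated to
    ``marker_level`` (mean counts per cell), ``n_shared_genes`` genes are
    elevated in two or three types each (lineage-adjacent populations share
    markers), and one pan marker is elevated in all types.  All remaining
    entries sit at ``off_level``.  Total panel size is
    ``n_types * markers_per_type + n_shared_genes + 1``; the defaults give the
    124-gene oligodendrocyte panel (13 * 9 + 6 + 1).

    The pan marker is expressed well above the type markers (``pan_level``,
    default four times ``marker_level``): the gating gene is chosen to be
    particularly highly expressed across the whole lineage, so a cell with a
    realistic transcript yield almost always carries at least one pan
    transcript.

    Reruns with identical arguments are bit-identical.
    """
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    if markers_per_type < 1:
        raise ValueError("markers_per_type must be >= 1")
    if n_shared_genes < 0:
        raise ValueError("n_shared_genes must be >= 0")
    if not marker_level > off_level:
        raise ValueError("marker_level must exceed off_level")
    if off_level < 0:
        raise ValueError("off_level must be >= 0")
    if pan_level is None:
        pan_level = 4.0 * marker_level
    if pan_level <= off_level:
        raise ValueError("pan_level must exceed off_level")

    types = list(type_ids) if type_ids is not None else _default_type_names(n_types)
    if len(types) != n_types:
        raise ValueError("type_ids length must equal n_types")

    rng = np.random.default_rng(seed)
    genes: list[str] = []
    n_genes = n_types * markers_per_type + n_shared_genes + 1
    expr = np.full((n_genes, n_types), off_level, dtype=float)

    row = 0
    for k, name in enumerate(types):
        for j in range(markers_per_type):
            genes.append(f"{name}-m{j + 1}")
            expr[row, k] = marker_level
            row += 1
    for j in range(n_shared_genes):
        genes.append(f"Shared-{j + 1}")
        n_carriers = int(rng.integers(2, min(3, n_types) + 1))
        carriers = rng.choice(n_types, size=n_carriers, replace=False)
        expr[row, carriers] = marker_level
        row += 1
    genes.append(pan_marker)
    expr[row, :] = pan_level

    return ReferenceProfiles(tuple(genes), tuple(types), expr, pan_marker)
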