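"""Probabilistic cell typing of decoded spots against reference profiles.

The pipeline assigns spots to segmented cells (nearest centroid within a
radius), turns per-cell gene counts into a posterior over cell types under
an independent-Poisson likelihood with per-cell exposure, and calls each
cell by the winner-takes-all rule after gating on the pan-lineage marker.

For cell c with gene counts n_cg and total N_c, the posterior over types is

    P(k | n_c) \propto prior(k) * prod_g Poisson(n_cg ; N_c * q_gk)

where q_gk is the reference profile of type k, pseudocounted and normalized
to sum to 1 over genes.  Computed in log space; a cell with no assigned
spots keeps the prior.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import logsumexp

from .profiles import ReferenceProfiles

BACKGROUND_CELL = 0  # assignment value for spots farther than max_radius

DEFAULT_MAX_RADIUS = 15.0   # um
DEFAULT_PSEUDOCOUNT = 1e-3


@dataclass
class TypingResult:
    """Per-cell gene counts, type posteriors, and the spot assignment map.

    ``cell_gene_counts``: cells x genes (index = cell_id).
    ``posterior``: cells x types; every row sums to 1.
    ``assigned_spots``: spot_id -> cell_id (0 = background).
    """

    cell_gene_counts: pd.DataFrame
    posterior: pd.DataFrame
    assigned_spots: pd.Series


def assign_spots_to_cells(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    max_radius: float = DEFAULT_MAX_RADIUS,
    gene_ids: tuple[str, ...] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Nearest-centroid spot assignment with a hard radius cut.

    Each spot goes to the closest cell centroid if within ``max_radius``
    (Euclidean, um), else to background.  Returns the assignment map and the
    cells x genes count matrix (all cells kept, zero rows included).
    """
    if max_radius <= 0:
        raise ValueError("max_radius must be > 0")
    if gene_ids is not None:
        unknown = set(spots["gene"]) - set(gene_ids)
        if unknown:
            raise ValueError(f"spots contain genes outside the panel: {sorted(unknown)[:5]}")
        genes = list(gene_ids)
    else:
        genes = sorted(set(spots["gene"]))

    cell_ids = cells["cell_id"].to_numpy()
    if len(cell_ids) != len(set(cell_ids)):
        raise ValueError("cell_ids must be unique")

    if len(cells) == 0:
        warnings.warn("empty cell table: all spots assigned to background")
        assignment = pd.Series(BACKGROUND_CELL, index=spots["spot_id"], name="cell_id")
        counts = pd.DataFrame(np.zeros((0, len(genes)), dtype=int), columns=genes)
        counts.index.name = "cell_id"
        return assignment, counts

    tree = cKDTree(cells[["x_um", "y_um"]].to_numpy())
    dist, idx = tree.query(spots[["x_um", "y_um"]].to_numpy())
    assigned = np.where(dist <= max_radius, cell_ids[idx], BACKGROUND_CELL)
    assignment = pd.Series(assigned, index=pd.Index(spots["spot_id"], name="spot_id"),
                           name="cell_id")

    gene_pos = {g: j for j, g in enumerate(genes)}
    mat = np.zeros((len(cells), len(genes)), dtype=int)
    keep = assigned != BACKGROUND_CELL
    row = idx[keep]
    col = spots["gene"].map(gene_pos).to_numpy()[keep]
    np.add.at(mat, (row, col), 1)
    counts = pd.DataFrame(mat, index=pd.Index(cell_ids, name="cell_id"), columns=genes)
    return assignment, counts


def compute_type_posteriors(
    cell_gene_counts: pd.DataFrame,
    profiles: ReferenceProfiles,
    prior: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Posterior over types per cell under the independent-Poisson model.

    The per-type mean for gene g is ``N_c * q_gk`` with q the pseudocounted,
    per-type-normalized reference profile, so the total expected count equals
    the observed N_c for every type and the exposure cancels; the posterior
    reduces to a multinomial likelihood over the panel.  Cells with zero
    counts get the prior row verbatim.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if tuple(cell_gene_counts.columns) != profiles.gene_ids:
        raise ValueError("count matrix gene axis does not match profiles.gene_ids")
    if prior is None:
        prior = np.full(profiles.n_types, 1.0 / profiles.n_types)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (profiles.n_types,) or abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError("prior must be a distribution over profiles.type_ids")

    counts = cell_gene_counts.to_numpy(dtype=float)
    q = profiles.normalized(pseudocount)           # genes x types
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior)
    loglik = counts @ np.log(q)                    # cells x types
    logpost = loglik + log_prior
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)

    empty = counts.sum(axis=1) == 0
    post[empty] = prior
    return pd.DataFrame(post, index=cell_gene_counts.index,
                        columns=list(profiles.type_ids))


def call_cells(
    typing: TypingResult,
    cells: pd.DataFrame,
    pan_marker: str,
    min_pan_count: int = 1,
    min_probability: float | None = None,
) -> pd.DataFrame:
    """Winner-takes-all type calls with pan-marker gating.

    Keeps cells whose assigned pan-marker count is at least
    ``min_pan_count``; each retained cell is called as the argmax of its
    posterior row (ties broken by panel type order).  ``min_probability``
    optionally drops calls below a posterior ceiling; by default nothing is
    dropped, low-certainty calls are only reported.

    Returns columns: cell_id, x_um, y_um, region, called_type,
    max_probability, pan_count.
    """
    if pan_marker not in typing.cell_gene_counts.columns:
        raise ValueError(f"pan marker {pan_marker!r} not in the count matrix")
    pan = typing.cell_gene_counts[pan_marker]
    post = typing.posterior
    winners = post.columns[np.argmax(post.to_numpy(), axis=1)]
    out = pd.DataFrame({
        "cell_id": post.index,
        "called_type": winners,
        "max_probability": post.to_numpy().max(axis=1),
        "pan_count": pan.reindex(post.index).to_numpy(),
    })
    meta_cols = ["cell_id", "x_um", "y_um"] + (
        ["region"] if "region" in cells.columns else [])
    out = out.merge(cells[meta_cols], on="cell_id", how="left")
    if "region" not in out.columns:
        out["region"] = "unassigned"
    out = out[out["pan_count"] >= min_pan_count]
    if min_probability is not None:
        out = out[out["max_probability"] >= min_probability]
    cols = ["cell_id", "x_um", "y_um", "region", "called_type",
            "max_probability", "pan_count"]
    return out[cols].reset_index(drop=True)


def mean_pie_charts(typing: TypingResult, called: pd.DataFrame,
                    co_occurrence: bool = False) -> pd.DataFrame:
    """Mean posterior per called type (rows: called type, columns: type).

    Row k averages the posterior vectors of cells called k, so it shows how
    often population k is "called with" the other populations; rows sum
    to 1.  With ``co_occurrence=True`` the alternative reading is used: the
    distribution of runner-up (second-highest) types among cells called k.
    A called type with zero cells yields a NaN row (flagged by a warning).
    """
    if len(called) == 0:
        raise ValueError("no called cells")
    post = typing.posterior.loc[called["cell_id"]]
    types = list(post.columns)
    out = pd.DataFrame(np.nan, index=types, columns=types)
    winner = called.set_index("cell_id")["called_type"]
    for k in types:
        members = post.loc[winner[winner == k].index]
        if len(members) == 0:
            continue
        if co_occurrence:
            arr = members.to_numpy().copy()
            arr[np.arange(len(arr)), np.argmax(arr, axis=1)] = -np.inf
            runner = np.argmax(arr, axis=1)
            row = np.bincount(runner, minlength=len(types)) / len(arr)
        else:
            row = members.mean(axis=0).to_numpy()
        out.loc[k] = row
    if out.isna().any(axis=1).any():
        missing = out.index[out.isna().any(axis=1)].tolist()
        warnings.warn(f"no cells called for types {missing}; rows undefined")
    return out


def confusion_matrix(typing: TypingResult, called: pd.DataFrame) -> pd.DataFrame:
    """Mean non-winning posterior mass, renormalized (diagonal = 0).

    For each cell called k, the posterior restricted to the losing types is
    rescaled to sum to 1 and averaged within the called type.  Cells with an
    exact one-hot posterior carry no information about confusion and are
    excluded; a row whose cells are all one-hot is NaN (flagged).
    """
    if len(called) == 0:
        raise ValueError("no called cells")
    post = typing.posterior.loc[called["cell_id"]]
    types = list(post.columns)
    out = pd.DataFrame(np.nan, index=types, columns=types)
    winner = called.set_index("cell_id")["called_type"]
    undefined = []
    for k in types:
        members = post.loc[winner[winner == k].index].to_numpy()
        if len(members) == 0:
            continue
        kk = types.index(k)
        rest = np.delete(members, kk, axis=1)
        mass = rest.sum(axis=1)
        informative = mass > 0
        if not informative.any():
            undefined.append(k)
            continue
        contrib = rest[informative] / mass[informative, None]
        row = np.zeros(len(types))
        row[np.arange(len(types)) != kk] = contrib.mean(axis=0)
        out.loc[k] = row
    if undefined:
        warnings.warn(f"all posteriors one-hot for {undefined}; rows undefined")
    return out
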