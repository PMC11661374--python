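"""Imaging-informed spot deconvolution and splitting.

The central idea: because the protein imaging and the barcoded-spot
sequencing come from the same tissue section, the cell-type composition of
every spot can be *counted* from registered, annotated imaging cells rather
than estimated by reference-only statistical fitting.  With per-spot
cell-type proportions ``beta[k, i]`` and a reference signature matrix
``mu[k, j]`` (mean expression of gene j in cell type k), each spot's counts
``x[i, j]`` are split into pure-cell-type sub-spots:

    xhat[i, j, k] = x[i, j] * beta[k, i] * mu[k, j] / sum_k' beta[k', i] * mu[k', j]

which conserves counts exactly (the sub-spots of a spot sum back to the
spot) and assigns each gene's counts to the types that both occupy the spot
and plausibly express the gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpotExpressionMatrix",
    "SpotProportionMatrix",
    "SubSpotExpressionTensor",
    "assign_cells_to_spots",
    "compute_proportions",
    "aggregate_signatures",
    "split_spots",
    "aggregate_codex_subspots",
]

UNASSIGNED = None  # sentinel value in assignment series for cells in gaps


@dataclass
class SpotExpressionMatrix:
    """Spot-by-gene counts plus the barcode-grid geometry.

    ``spots`` must have columns ``spot_id``, ``row``, ``col`` (barcode grid
    indices) and ``x``, ``y`` (spot center coordinates, pixels).
    ``pixel_size`` is the spot side length; ``pitch`` the center-to-center
    channel spacing (defaults to ``pixel_size`` when channels abut).
    """

    counts: np.ndarray
    spots: pd.DataFrame
    genes: list
    pixel_size: float
    pitch: float | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        n_spots, n_genes = self.counts.shape
        if len(self.spots) != n_spots:
            raise ValueError(
                f"spot table has {len(self.spots)} rows but matrix declares {n_spots} spots"
            )
        if len(self.genes) != n_genes:
            raise ValueError(
                f"gene list has {len(self.genes)} names but matrix declares {n_genes} genes"
            )
        if len(set(self.genes)) != n_genes:
            raise ValueError("gene names must be unique")
        if self.spots["spot_id"].duplicated().any():
            dups = self.spots.loc[self.spots["spot_id"].duplicated(), "spot_id"].tolist()
            raise ValueError(f"duplicate spot ids: {dups[:5]}")
        if self.pitch is None:
            self.pitch = float(self.pixel_size)

    @property
    def spot_ids(self) -> list:
        return self.spots["spot_id"].tolist()

    def grid_origin(self) -> tuple[float, float]:
        """Center coordinate of the (row=0, col=0) lattice position."""
        s = self.spots
        x0 = float((s["x"] - s["col"] * self.pitch).iloc[0])
        y0 = float((s["y"] - s["row"] * self.pitch).iloc[0])
        return x0, y0


def assign_cells_to_spots(cells: pd.DataFrame, spot_matrix: SpotExpressionMatrix) -> pd.Series:
    """Map each cell centroid to the spot whose footprint contains it.

    A cell belongs to spot (row a, col b) iff its centroid lies in the
    half-open square ``[cx - w/2, cx + w/2) x [cy - w/2, cy + w/2)`` with
    ``w = pixel_size`` centered at the spot; cells falling in inter-channel
    gaps (or outside the grid) are unassigned (value None).  Footprints are
    disjoint when ``w <= pitch``, so each cell maps to at most one spot.

    ``cells`` needs columns ``cell_id``, ``x``, ``y`` (coordinates already in
    the spot frame, i.e. post-registration).
    """
    w = float(spot_matrix.pixel_size)
    pitch = float(spot_matrix.pitch)
    if w > pitch:
        raise ValueError(
            f"spot footprints overlap: pixel_size {w} exceeds pitch {pitch}"
        )
    x0, y0 = spot_matrix.grid_origin()
    spot_lookup = {
        (int(a), int(b)): sid
        for a, b, sid in zip(spot_matrix.spots["row"], spot_matrix.spots["col"], spot_matrix.spots["spot_id"])
    }
    xs = cells["x"].to_numpy(dtype=float)
    ys = cells["y"].to_numpy(dtype=float)
    # nearest lattice index; the +pitch/2 floor makes the tie at a midpoint
    # between two channels land on the upper spot, consistent with the
    # half-open footprint when w == pitch
    bs = np.floor((xs - x0 + pitch / 2.0) / pitch).astype(int)
    as_ = np.floor((ys - y0 + pitch / 2.0) / pitch).astype(int)
    cx = x0 + bs * pitch
    cy = y0 + as_ * pitch
    inside = (
        (xs >= cx - w / 2.0)
        & (xs < cx + w / 2.0)
        & (ys >= cy - w / 2.0)
        & (ys < cy + w / 2.0)
    )
    out = []
    for a, b, ok in zip(as_, bs, inside):
        out.append(spot_lookup.get((int(a), int(b))) if ok else None)
    return pd.Series(out, index=pd.Index(cells["cell_id"], name="cell_id"), name="spot_id", dtype=object)


@dataclass
class SpotProportionMatrix:
    """Cell-type proportions beta[k, i] per spot, from counted cells."""

    beta: pd.DataFrame  # index: type names, columns: spot ids
    n_cells: pd.Series  # assigned-cell count per spot
    empty: pd.Series = field(init=False)  # True where no cell was assigned

    def __post_init__(self):
        self.empty = self.n_cells == 0
        colsums = self.beta.to_numpy().sum(axis=0)
        occupied = ~self.empty.to_numpy()
        if occupied.any() and np.max(np.abs(colsums[occupied] - 1.0)) > 1e-9:
            raise ValueError("proportions of occupied spots must sum to 1")

    @property
    def types(self) -> list:
        return self.beta.index.tolist()


def compute_proportions(
    assignment: pd.Series,
    cell_labels: pd.Series,
    type_universe,
    spot_ids,
) -> SpotProportionMatrix:
    """beta[k, i] = (# cells of type k in spot i) / (# cells in spot i).

    ``assignment`` maps cell_id -> spot_id (None = unassigned), as produced
    by :func:`assign_cells_to_spots`.  Every assigned cell must carry a label
    from ``type_universe``.  Spots with no assigned cell get an all-zero
    column and are flagged empty.
    """
    type_universe = list(type_universe)
    spot_ids = list(spot_ids)
    assigned = assignment[assignment.notna()]
    labels = cell_labels.reindex(assigned.index)
    bad = labels.index[labels.isna() | ~labels.isin(type_universe)].tolist()
    if bad:
        raise ValueError(
            f"{len(bad)} assigned cells are unlabeled or have labels outside the "
            f"type universe; first offenders: {bad[:10]}"
        )
    counts = pd.crosstab(labels, assigned)
    counts = counts.reindex(index=type_universe, columns=spot_ids, fill_value=0).astype(float)
    n_cells = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = counts.div(n_cells.where(n_cells > 0), axis=1).fillna(0.0)
    n_cells = n_cells.astype(int)
    n_cells.index.name = "spot_id"
    return SpotProportionMatrix(beta=beta, n_cells=n_cells)


def aggregate_signatures(reference_expression: pd.DataFrame, reference_labels: pd.Series) -> pd.DataFrame:
    """Signature matrix mu[k, j]: per-type arithmetic mean of reference profiles.

    ``reference_expression`` is profiles x genes; values are used on whatever
    normalization scale they arrive on (per-gene scaling cancels in the
    splitting formula, so none is imposed here).
    """
    labels = reference_labels.reindex(reference_expression.index)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"unlabeled reference profiles: {missing[:10]}")
    mu = reference_expression.groupby(labels, observed=True).mean()
    mu.index.name = "type"
    if (mu.to_numpy().sum(axis=1) == 0).any():
        zero = mu.index[mu.to_numpy().sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero signature rows for types: {zero}")
    return mu


@dataclass
class SubSpotExpressionTensor:
    """Spot counts split into pure-cell-type sub-spots.

    ``tensor`` has shape (spots, genes, types).  ``unassigned`` (spots x
    genes) holds counts routed to no type under the "drop" degenerate-gene
    policy; it is all zero under the default "beta" policy.
    """

    tensor: np.ndarray
    spot_ids: list
    genes: list
    types: list
    beta: pd.DataFrame
    unassigned: np.ndarray

    def flattened(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """One row per (spot, type) with beta > 0.

        Returns ``(keys, matrix)``: keys has columns spot_id/type, matrix is
        the matching sub-spot x gene expression frame.
        """
        rows = []
        data = []
        beta = self.beta.to_numpy()
        for i, sid in enumerate(self.spot_ids):
            for k, t in enumerate(self.types):
                if beta[k, i] > 0:
                    rows.append((sid, t))
                    data.append(self.tensor[i, :, k])
        keys = pd.DataFrame(rows, columns=["spot_id", "type"])
        matrix = pd.DataFrame(np.asarray(data).reshape(len(rows), len(self.genes)), columns=self.genes)
        return keys, matrix


def split_spots(
    spot_matrix: SpotExpressionMatrix,
    proportions: SpotProportionMatrix,
    mu: pd.DataFrame,
    zero_denominator_policy: str = "beta",
) -> SubSpotExpressionTensor:
    """Split each spot's gene counts into pure-cell-type sub-spots.

    Genes are aligned with ``mu`` by exact (case-sensitive) name match;
    genes absent from the signature matrix are dropped with a logged count.
    For a gene j whose denominator ``sum_k beta[k,i] mu[k,j]`` is zero in an
    occupied spot with counts present, the ``zero_denominator_policy``
    applies: ``"beta"`` (default) splits those counts by the proportions
    alone, preserving conservation; ``"drop"`` routes them to an explicit
    unassigned bucket.  Empty spots produce no sub-spots.
    """
    if zero_denominator_policy not in ("beta", "drop"):
        raise ValueError(f"unknown zero_denominator_policy {zero_denominator_policy!r}")
    types = proportions.types
    missing_types = [t for t in types if t not in mu.index]
    if missing_types:
        raise ValueError(
            f"types present in proportions but absent from the signature matrix: {missing_types}"
        )
    shared_genes = [g for g in spot_matrix.genes if g in mu.columns]
    n_dropped = len(spot_matrix.genes) - len(shared_genes)
    if n_dropped:
        logger.warning("dropping %d genes absent from the signature matrix", n_dropped)
    if not shared_genes:
        raise ValueError("no genes shared between spot matrix and signature matrix")

    gene_idx = [spot_matrix.genes.index(g) for g in shared_genes]
    x = np.asarray(spot_matrix.counts, dtype=float)[:, gene_idx]  # (S, J)
    spot_ids = spot_matrix.spot_ids
    beta = proportions.beta.reindex(columns=spot_ids).to_numpy(dtype=float)  # (K, S)
    mu_arr = mu.loc[types, shared_genes].to_numpy(dtype=float)  # (K, J)
    if np.any(mu_arr < 0):
        raise ValueError("signature matrix must be nonnegative")

    weights = beta.T[:, None, :] * mu_arr.T[None, :, :]  # (S, J, K)
    denom = weights.sum(axis=2)  # (S, J)
    occupied = (~proportions.empty.reindex(spot_ids).to_numpy())[:, None]  # (S, 1)
    tensor = np.zeros_like(weights)
    unassigned = np.zeros_like(x)

    ok = (denom > 0) & occupied
    np.divide(
        x[:, :, None] * weights,
        denom[:, :, None],
        out=tensor,
        where=ok[:, :, None],
    )
    degenerate = occupied & (denom == 0) & (x > 0)
    if degenerate.any():
        logger.warning(
            "%d (spot, gene) entries have a zero signature denominator; policy=%s",
            int(degenerate.sum()),
            zero_denominator_policy,
        )
        if zero_denominator_policy == "beta":
            tensor += np.where(degenerate[:, :, None], x[:, :, None] * beta.T[:, None, :], 0.0)
        else:
            unassigned = np.where(degenerate, x, 0.0)
    return SubSpotExpressionTensor(
        tensor=tensor,
        spot_ids=spot_ids,
        genes=shared_genes,
        types=types,
        beta=proportions.beta.reindex(columns=spot_ids),
        unassigned=unassigned,
    )


def aggregate_codex_subspots(
    normalized_cells: pd.DataFrame,
    assignment: pd.Series,
    labels: pd.Series,
    marker_columns=None,
) -> pd.DataFrame:
    """Aggregate imaging cells into pure-cell-type protein sub-spots.

    One row per (spot_id, type) with at least one assigned cell; values are
    the mean normalized marker signal over those cells.  The row keys match
    the (spot, type) keys of the RNA sub-spots derived from the same
    assignment, so the two modalities join 1:1 where both exist.
    """
    if marker_columns is None:
        reserved = {"cell_id", "x", "y", "area", "type", "label", "spot_id"}
        marker_columns = [c for c in normalized_cells.columns if c not in reserved]
    cells = normalized_cells.set_index("cell_id") if "cell_id" in normalized_cells.columns else normalized_cells
    spot = assignment.reindex(cells.index)
    lab = labels.reindex(cells.index)
    keep = spot.notna() & lab.notna()
    if not keep.any():
        warnings.warn("no assigned, labeled cells to aggregate")
        return pd.DataFrame(columns=marker_columns, index=pd.MultiIndex.from_arrays([[], []], names=["spot_id", "type"]))
    sub = cells.loc[keep, marker_columns]
    grouped = sub.groupby([spot[keep], lab[keep]], observed=True).mean()
    grouped.index.names = ["spot_id", "type"]
    return grouped
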