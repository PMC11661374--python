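"""Per-cell protein feature extraction, QC filtering and normalization.

Features are extracted from a segmentation label mask and a multichannel
image stack by summing each channel's signal under each cell label.  QC
keeps cells inside the [0.05, 0.95] cell-size quantile range whose nuclear
(DAPI) signal strictly exceeds the 0.1 quantile.  Each marker is then
area-normalized and scaled to [0, 1] between its 5th and 95th percentiles,
with values outside that range clipped to 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "NormalizationRecord",
    "extract_cell_features",
    "filter_cells",
    "normalize_features",
]

RESERVED_COLUMNS = ("cell_id", "x", "y", "area", "type", "label", "spot_id")


def marker_columns(cells: pd.DataFrame) -> list:
    """Columns of a cell table holding marker signal (everything non-reserved)."""
    return [c for c in cells.columns if c not in RESERVED_COLUMNS]


def extract_cell_features(label_mask, channel_stack, channel_names) -> pd.DataFrame:
    """Sum each channel's pixel signal under each segmentation label.

    ``label_mask`` is a 2-D integer mask (0 = background); ``channel_stack``
    is (n_channels, H, W) matching the mask shape.  Returns one row per
    nonzero label with columns cell_id, x, y (centroid = mean pixel
    coordinate, x = column), area (pixel count) and one raw-signal column
    per channel name.
    """
    mask = np.asarray(label_mask)
    stack = np.asarray(channel_stack, dtype=float)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[1:] != mask.shape:
        raise ValueError(
            f"channel stack shape {stack.shape[1:]} does not match mask shape {mask.shape}"
        )
    channel_names = list(channel_names)
    if len(channel_names) != stack.shape[0]:
        raise ValueError(
            f"{len(channel_names)} channel names for {stack.shape[0]} channels"
        )
    labels = np.unique(mask)
    labels = labels[labels != 0]
    if labels.size == 0:
        warnings.warn("empty label mask: no cells extracted")
        return pd.DataFrame(columns=["cell_id", "x", "y", "area"] + channel_names)
    areas = ndimage.sum_labels(np.ones_like(mask, dtype=float), mask, labels)
    cy, cx = zip(*ndimage.center_of_mass(np.ones_like(mask, dtype=float), mask, labels))
    out = pd.DataFrame(
        {
            "cell_id": [f"cell{int(l)}" for l in labels],
            "x": np.asarray(cx, dtype=float),
            "y": np.asarray(cy, dtype=float),
            "area": areas.astype(float),
        }
    )
    for name, channel in zip(channel_names, stack):
        out[name] = ndimage.sum_labels(channel, mask, labels)
    return out


def filter_cells(
    cells: pd.DataFrame,
    dapi_channel: str | None,
    size_quantile_range: tuple = (0.05, 0.95),
    dapi_quantile: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """QC filter: size within quantile range, nuclear signal above threshold.

    Retains cells whose area lies in the closed interval
    ``[q_lo(area), q_hi(area)]`` *and* whose raw DAPI signal is strictly
    greater than the ``dapi_quantile`` quantile.  Quantiles use linear
    interpolation between order statistics.  ``dapi_channel=None`` applies
    the size rule alone.  Returns the filtered table and the thresholds used
    (re-applying them reproduces the retained set).
    """
    if dapi_channel is not None and dapi_channel not in cells.columns:
        raise KeyError(f"DAPI channel {dapi_channel!r} not in cell table")
    if cells.empty:
        warnings.warn("empty cell table passed to filter_cells")
        return cells.copy(), {"area_lo": np.nan, "area_hi": np.nan, "dapi_threshold": np.nan}
    lo, hi = size_quantile_range
    area = cells["area"].to_numpy(dtype=float)
    area_lo, area_hi = np.quantile(area, [lo, hi])
    keep = (area >= area_lo) & (area <= area_hi)
    dapi_thr = np.nan
    if dapi_channel is not None:
        dapi = cells[dapi_channel].to_numpy(dtype=float)
        dapi_thr = float(np.quantile(dapi, dapi_quantile))
        keep &= dapi > dapi_thr
    thresholds = {
        "area_lo": float(area_lo),
        "area_hi": float(area_hi),
        "dapi_threshold": dapi_thr,
        "size_quantile_range": [float(lo), float(hi)],
        "dapi_quantile": float(dapi_quantile),
        "n_in": int(len(cells)),
        "n_out": int(keep.sum()),
    }
    return cells.loc[keep].reset_index(drop=True), thresholds


@dataclass
class NormalizationRecord:
    """Per-marker quantile anchors used for the [0, 1] scaling."""

    q05: dict
    q95: dict
    area_normalized: bool
    quantiles: tuple = (0.05, 0.95)
    quantile_method: str = "linear"
    degenerate_markers: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "q05": self.q05,
            "q95": self.q95,
            "area_normalized": self.area_normalized,
            "quantiles": list(self.quantiles),
            "quantile_method": self.quantile_method,
            "degenerate_markers": self.degenerate_markers,
        }


def normalize_features(
    cells: pd.DataFrame,
    markers=None,
    area_normalize: bool = True,
    q: tuple = (0.05, 0.95),
) -> tuple[pd.DataFrame, NormalizationRecord]:
    """Scale each marker to [0, 1] between its low/high quantiles.

    Working value v = raw / area (if ``area_normalize``) else raw; output is
    ``clip((v - q_lo) / (q_hi - q_lo), 0, 1)`` per marker.  A marker whose
    two quantiles coincide carries no signal at this scaling and is set to 0
    for all cells (with a warning).  Returns a table with marker columns
    replaced by normalized values, plus the record needed to re-apply the
    identical scaling.
    """
    if markers is None:
        markers = marker_columns(cells)
    if area_normalize and (cells["area"] <= 0).any():
        raise ValueError("areas must be positive for area normalization")
    out = cells.copy()
    q_lo_map, q_hi_map, degenerate = {}, {}, []
    lo, hi = q
    for m in markers:
        v = cells[m].to_numpy(dtype=float)
        if area_normalize:
            v = v / cells["area"].to_numpy(dtype=float)
        q_lo, q_hi = np.quantile(v, [lo, hi])
        q_lo_map[m], q_hi_map[m] = float(q_lo), float(q_hi)
        if q_hi == q_lo:
            degenerate.append(m)
            warnings.warn(f"marker {m!r} has a degenerate quantile range; set to 0")
            out[m] = 0.0
        else:
            out[m] = np.clip((v - q_lo) / (q_hi - q_lo), 0.0, 1.0)
    record = NormalizationRecord(
        q05=q_lo_map,
        q95=q_hi_map,
        area_normalized=bool(area_normalize),
        quantiles=(float(lo), float(hi)),
        degenerate_markers=degenerate,
    )
    return out, record
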