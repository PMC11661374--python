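"""Quality metrics: cross-slice marker reproducibility, ASW and ARI.

Cross-slice reproducibility follows the landmark-registration protocol:
cells from slice A are mapped into slice B's frame, both slices are
discretized into square spatial bins, per-bin marker means are computed,
and a Pearson correlation per marker is taken over the bins occupied in
both slices.  Cluster-quality scoring wraps the average silhouette width
(ASW) and adjusted Rand index (ARI) with the conventions used throughout
the package (singleton clusters contribute silhouette 0; undefined
correlations reported as missing, never as 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .codex import marker_columns

__all__ = [
    "binned_marker_correlation",
    "average_silhouette_width",
    "adjusted_rand_index",
]


def _bin_means(cells: pd.DataFrame, markers, bin_size: float) -> pd.DataFrame:
    bx = np.floor(cells["x"].to_numpy(dtype=float) / bin_size).astype(int)
    by = np.floor(cells["y"].to_numpy(dtype=float) / bin_size).astype(int)
    key = pd.MultiIndex.from_arrays([by, bx], names=["bin_row", "bin_col"])
    return cells[list(markers)].set_axis(key).groupby(level=["bin_row", "bin_col"]).mean()


def binned_marker_correlation(
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    transform_a_to_b=None,
    bin_size: float = 100.0,
    markers=None,
) -> tuple[pd.Series, int]:
    """Per-marker Pearson correlation of bin-averaged signal across slices.

    Slice A coordinates are mapped into slice B's frame (the fixed slice
    hosts the bin grid), both slices are binned at ``bin_size`` px with bin
    index ``floor(coordinate / bin_size)`` per axis, and correlations are
    computed over bins occupied in both slices.  Markers constant over the
    common bins in either slice get NaN (undefined, not 0).  Returns the
    per-marker correlations and the number of common bins.
    """
    if markers is None:
        markers = sorted(set(marker_columns(cells_a)) & set(marker_columns(cells_b)))
    if not markers:
        raise ValueError("no shared marker columns between the two slices")
    a = cells_a.copy()
    if transform_a_to_b is not None:
        pts = transform_a_to_b.apply(a[["x", "y"]].to_numpy())
        a["x"], a["y"] = pts[:, 0], pts[:, 1]
    means_a = _bin_means(a, markers, bin_size)
    means_b = _bin_means(cells_b, markers, bin_size)
    common = means_a.index.intersection(means_b.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common bins; correlation is meaningless")
    va = means_a.loc[common].to_numpy(dtype=float)
    vb = means_b.loc[common].to_numpy(dtype=float)
    out = {}
    for i, m in enumerate(markers):
        x, y = va[:, i], vb[:, i]
        if x.std() == 0 or y.std() == 0:
            out[m] = np.nan
        else:
            out[m] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="pearson_r"), int(len(common))


def average_silhouette_width(embedding, labels) -> float:
    """Mean silhouette over all points (Euclidean distance).

    Points in singleton clusters contribute 0, the common convention.
    Requires at least 3 points and 2 distinct labels.
    """
    emb = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if emb.ndim == 1:
        emb = emb[:, None]
    if len(labels) != len(emb):
        raise ValueError("embedding and labels differ in length")
    if len(emb) < 3:
        raise ValueError("need at least 3 points for a silhouette")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 distinct labels")
    return float(np.mean(silhouette_samples(emb, labels, metric="euclidean")))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    return float(adjusted_rand_score(a, b))
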