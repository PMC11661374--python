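"""Cross-modality cell-type annotation via pivot matching.

Transfers reference (scRNA-seq) cell-type labels onto imaging cells in
three steps: (1) identify linked gene/protein feature pairs and screen out
near-constant ones (std <= 0.01); (2) find high-confidence cross-modality
"pivot" pairs by neighborhood-smoothed, jointly reduced linked features and
mutual-nearest-neighbor matching, keeping roughly the top 10% of imaging
cells by match score; (3) transfer labels to the pivots and propagate to
all remaining cells with an SVM trained on the pivots' protein features.

The pivot matcher is a deliberately simplified integration step: it keeps
the pipeline role and the headline parameters (smoothing weight 0.3, ~10%
pivots, std > 0.01 screen) of full iterative cross-modal matching methods
without their refinement machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "LinkedFeatureSet",
    "PivotSet",
    "link_features",
    "match_pivots",
    "transfer_labels",
    "propagate_labels",
]


@dataclass
class LinkedFeatureSet:
    """Gene/protein feature pairs usable for cross-modality matching."""

    pairs: list  # [(gene_name, protein_name), ...] retained
    stds: pd.DataFrame  # per candidate pair: gene_std, protein_std, retained
    dropped: list = field(default_factory=list)  # [(gene, protein, reason)]

    @property
    def genes(self) -> list:
        return [g for g, _ in self.pairs]

    @property
    def proteins(self) -> list:
        return [p for _, p in self.pairs]


def link_features(
    reference: pd.DataFrame,
    codex: pd.DataFrame,
    alias_map: dict | None = None,
    std_threshold: float = 0.01,
) -> LinkedFeatureSet:
    """Pair reference genes with imaging proteins by name and screen by std.

    Candidate pairs are exact column-name matches plus ``alias_map`` entries
    (protein name -> gene name, e.g. CD20 -> MS4A1).  A pair is retained
    only if the feature's standard deviation exceeds ``std_threshold`` in
    *both* modalities (near-constant features carry no matching signal);
    dropped pairs are logged with the failing side.
    """
    alias_map = alias_map or {}
    gene_set = set(reference.columns)
    candidates = []
    for protein in codex.columns:
        gene = alias_map.get(protein, protein)
        if gene in gene_set:
            candidates.append((gene, protein))
    rows, retained, dropped = [], [], []
    for gene, protein in candidates:
        g_std = float(reference[gene].std(ddof=0))
        p_std = float(codex[protein].std(ddof=0))
        ok = g_std > std_threshold and p_std > std_threshold
        rows.append({"gene": gene, "protein": protein, "gene_std": g_std, "protein_std": p_std, "retained": ok})
        if ok:
            retained.append((gene, protein))
        else:
            side = "gene" if g_std <= std_threshold else "protein"
            dropped.append((gene, protein, f"{side} std <= {std_threshold}"))
            logger.info("dropping linked pair (%s, %s): %s std too low", gene, protein, side)
    if not retained:
        raise ValueError(
            "no linked features retained: integration impossible "
            f"({len(candidates)} candidates, all failed the std > {std_threshold} screen or none matched)"
        )
    return LinkedFeatureSet(pairs=retained, stds=pd.DataFrame(rows), dropped=dropped)


@dataclass
class PivotSet:
    """High-confidence cross-modality matches (one per imaging cell at most)."""

    matches: pd.DataFrame  # columns: cell_id, profile_id, score; sorted by score desc
    pivot_fraction: float
    n_components: int

    @property
    def cell_ids(self) -> list:
        return self.matches["cell_id"].tolist()


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def _smooth(linked: np.ndarray, full: np.ndarray, weight: float, n_neighbors: int) -> np.ndarray:
    """Replace each cell's linked-feature vector by a graph-smoothed version.

    Neighbors come from a k-NN graph on the *full* standardized feature set
    of the modality; the smoothed vector is
    ``(1 - w) * self + w * mean(neighbors)``.
    """
    if weight == 0:
        return linked
    k = min(n_neighbors + 1, full.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(full)
    _, idx = nn.kneighbors(full)
    neighbor_mean = linked[idx[:, 1:]].mean(axis=1) if k > 1 else linked
    return (1.0 - weight) * linked + weight * neighbor_mean


def _choose_components(singular_explained: np.ndarray, target: float = 0.8) -> int:
    cum = np.cumsum(singular_explained)
    return int(np.searchsorted(cum, target) + 1)


def match_pivots(
    reference_matrix: pd.DataFrame,
    codex_matrix: pd.DataFrame,
    linked: LinkedFeatureSet,
    smoothing_weight: float = 0.3,
    n_components: int | None = None,
    pivot_fraction: float = 0.10,
    n_neighbors: int = 15,
    match_neighbors: int = 5,
    seed: int = 0,
    reference_labels: pd.Series | None = None,
) -> PivotSet:
    """Find high-confidence reference-profile/imaging-cell pairs.

    Both matrices are standardized per feature internally.  Linked-feature
    vectors are smoothed over within-modality k-NN graphs (weight 0.3 by
    default, compensating the weak linkage between modalities), jointly
    reduced by a shared PCA, and matched by mutual nearest neighbors in the
    reduced space.  The top ``pivot_fraction`` of imaging cells by match
    score (negative Euclidean distance; ties broken by cell id) become
    pivots.  Deterministic given ``seed``.

    Rare cell types tend to have sparser reference clusters and therefore
    systematically worse match scores, so a purely global score cut can
    leave a type with no pivots at all.  When ``reference_labels`` is
    supplied, selection is stratified: each matched label receives a slot
    quota proportional to its share of the mutual-match pool (at least one),
    filled by score; leftover slots go to the best remaining matches
    globally.  With ``reference_labels=None`` the plain global score rule
    applies.
    """
    if not linked.pairs:
        raise ValueError("empty linked feature set")
    ref_full = _standardize(reference_matrix.to_numpy(dtype=float))
    cdx_full = _standardize(codex_matrix.to_numpy(dtype=float))
    ref_linked = _standardize(reference_matrix[linked.genes].to_numpy(dtype=float))
    cdx_linked = _standardize(codex_matrix[linked.proteins].to_numpy(dtype=float))

    ref_s = _smooth(ref_linked, ref_full, smoothing_weight, n_neighbors)
    cdx_s = _smooth(cdx_linked, cdx_full, smoothing_weight, n_neighbors)

    joint = np.vstack([ref_s, cdx_s])
    n_feat = joint.shape[1]
    probe = PCA(n_components=min(n_feat, joint.shape[0]), svd_solver="full", random_state=seed).fit(joint)
    if n_components is None:
        n_components = _choose_components(probe.explained_variance_ratio_)
    if n_components > n_feat:
        raise ValueError(f"n_components {n_components} exceeds {n_feat} retained linked features")
    reduced = probe.transform(joint)[:, :n_components]
    ref_r = reduced[: len(ref_s)]
    cdx_r = reduced[len(ref_s):]

    k = min(match_neighbors, len(ref_r), len(cdx_r))
    nn_ref = NearestNeighbors(n_neighbors=k).fit(ref_r)
    nn_cdx = NearestNeighbors(n_neighbors=k).fit(cdx_r)
    d_c2r, i_c2r = nn_ref.kneighbors(cdx_r)  # for each codex cell, nearest refs
    _, i_r2c = nn_cdx.kneighbors(ref_r)  # for each ref, nearest codex cells
    ref_neighbor_sets = [set(row) for row in i_r2c]

    cell_ids = list(codex_matrix.index)
    profile_ids = list(reference_matrix.index)
    records = []
    for c in range(len(cdx_r)):
        best = None
        for d, r in zip(d_c2r[c], i_c2r[c]):
            if c in ref_neighbor_sets[r]:  # mutual
                if best is None or d < best[0]:
                    best = (d, r)
        if best is not None:
            records.append({"cell_id": cell_ids[c], "profile_id": profile_ids[best[1]], "score": -float(best[0])})
    matches = pd.DataFrame(records, columns=["cell_id", "profile_id", "score"])
    matches = matches.sort_values(["score", "cell_id"], ascending=[False, True], kind="mergesort")
    n_keep = min(len(matches), int(round(pivot_fraction * len(cell_ids))))
    if reference_labels is None or matches.empty:
        matches = matches.head(n_keep)
    else:
        labels = reference_labels.reindex(matches["profile_id"])
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()
            raise ValueError(f"reference profiles without labels: {missing[:10]}")
        labels = pd.Series(labels.to_numpy(), index=matches.index)
        quota = {
            lab: max(1, int(np.floor(n_keep * n_lab / len(matches))))
            for lab, n_lab in labels.value_counts().items()
        }
        picked = []
        for lab, grp in matches.groupby(labels, sort=True):
            picked.append(grp.head(quota[lab]))
        selected = pd.concat(picked)
        leftover = matches.drop(selected.index).head(max(0, n_keep - len(selected)))
        matches = (
            pd.concat([selected, leftover])
            .sort_values(["score", "cell_id"], ascending=[False, True], kind="mergesort")
        )
    matches = matches.reset_index(drop=True)
    logger.info("retained %d pivot pairs (%.1f%% of imaging cells)", n_keep, 100 * n_keep / max(1, len(cell_ids)))
    return PivotSet(matches=matches, pivot_fraction=pivot_fraction, n_components=int(n_components))


def transfer_labels(pivots: PivotSet, reference_labels: pd.Series) -> pd.Series:
    """Carry each matched reference profile's label onto its pivot cell."""
    labels = reference_labels.reindex(pivots.matches["profile_id"])
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"reference profiles without labels: {missing[:10]}")
    out = pd.Series(labels.to_numpy(), index=pd.Index(pivots.matches["cell_id"], name="cell_id"), name="label")
    return out


def propagate_labels(
    labeled_pivots: pd.Series,
    all_cells_normalized: pd.DataFrame,
    classifier: str = "svm",
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> tuple[pd.DataFrame, dict]:
    """Extend pivot labels to every cell with a supervised classifier.

    An SVM (balanced class weights) is trained on the pivot cells' normalized
    protein features.  A stratified hold-out split of the pivots reports
    per-class and macro F1 before the final model (fit on all pivots)
    predicts the non-pivot cells.  Returns a per-cell table (label,
    is_pivot) indexed like ``all_cells_normalized`` plus the F1 metrics.
    """
    if classifier != "svm":
        raise ValueError(f"unsupported classifier {classifier!r}")
    classes = labeled_pivots.value_counts()
    if len(classes) < 2:
        raise ValueError("need pivots from at least two classes to train a classifier")
    if (classes < 2).any():
        small = classes.index[classes < 2].tolist()
        raise ValueError(f"classes with fewer than 2 pivots (cannot hold out): {small}")
    features = all_cells_normalized.loc[labeled_pivots.index].to_numpy(dtype=float)
    y = labeled_pivots.to_numpy()

    x_tr, x_te, y_tr, y_te = train_test_split(
        features, y, test_size=holdout_fraction, stratify=y, random_state=seed
    )
    probe = SVC(kernel="rbf", class_weight="balanced", random_state=seed).fit(x_tr, y_tr)
    label_order = sorted(classes.index)
    per_class = f1_score(y_te, probe.predict(x_te), labels=label_order, average=None, zero_division=0)
    metrics = {
        "per_class_f1": dict(zip(label_order, map(float, per_class))),
        "macro_f1": float(np.mean(per_class)),
        "n_pivots": int(len(y)),
        "n_holdout": int(len(y_te)),
    }

    final = SVC(kernel="rbf", class_weight="balanced", random_state=seed).fit(features, y)
    is_pivot = all_cells_normalized.index.isin(labeled_pivots.index)
    labels = pd.Series(index=all_cells_normalized.index, dtype=object, name="label")
    labels.loc[labeled_pivots.index] = labeled_pivots
    if (~is_pivot).any():
        labels.loc[~is_pivot] = final.predict(all_cells_normalized.loc[~is_pivot].to_numpy(dtype=float))
    out = pd.DataFrame({"label": labels, "is_pivot": is_pivot})
    return out, metrics
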