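"""Linked features, pivot matching, label transfer and propagation."""

import numpy as np
import pandas as pd
import pytest

from spotsplit import annotation as ann
from spotsplit import codex, synthetic as syn


def two_modality_toy(n_per_type=40, n_extra=3, noise=0.0, seed=0):
    """Two well-separated types measured identically in both modalities."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0, 5.0], [5.0, 5.0, 0.0]])
    rows_ref, rows_cdx, types = [], [], []
    for k in range(2):
        rows_ref.append(centers[k] + noise * rng.normal(size=(n_per_type, 3)))
        rows_cdx.append(centers[k] + noise * rng.normal(size=(n_per_type, 3)))
        types += [f"T{k}"] * n_per_type
    ref = pd.DataFrame(np.vstack(rows_ref), columns=["g1", "g2", "g3"],
                       index=[f"r{i}" for i in range(2 * n_per_type)])
    cdx = pd.DataFrame(np.vstack(rows_cdx), columns=["p1", "p2", "p3"],
                       index=[f"c{i}" for i in range(2 * n_per_type)])
    if n_extra:
        ref[[f"gx{i}" for i in range(n_extra)]] = rng.normal(size=(len(ref), n_extra))
        cdx[[f"px{i}" for i in range(n_extra)]] = rng.normal(size=(len(cdx), n_extra))
    labels = pd.Series(types, index=ref.index, name="type")
    truth_cdx = pd.Series(types, index=cdx.index, name="type")
    alias = {"p1": "g1", "p2": "g2", "p3": "g3"}
    return ref, cdx, labels, truth_cdx, alias


class TestLinkFeatures:
    def test_alias_resolution(self):
        ref = pd.DataFrame({"MS4A1": [0.0, 1.0, 2.0]})
        cdx = pd.DataFrame({"CD20": [0.0, 0.5, 1.0]})
        linked = ann.link_features(ref, cdx, {"CD20": "MS4A1"})
        assert linked.pairs == [("MS4A1", "CD20")]

    def test_constant_feature_dropped(self):
        ref = pd.DataFrame({"A": [0.0, 1.0], "B": [1.0, 2.0]})
        cdx = pd.DataFrame({"A": [5.0, 5.0], "B": [0.0, 3.0]})
        linked = ann.link_features(ref, cdx)
        assert linked.pairs == [("B", "B")]
        assert linked.dropped[0][:2] == ("A", "A")

    def test_std_screen_matches_bruteforce(self, rng):
        n = 30
        ref = pd.DataFrame(rng.normal(size=(50, n)), columns=[f"f{i}" for i in range(n)])
        cdx = pd.DataFrame(rng.normal(size=(50, n)), columns=[f"f{i}" for i in range(n)])
        flat = rng.choice(n, 5, replace=False)
        for i in flat:
            cdx[f"f{i}"] = 1.0
        linked = ann.link_features(ref, cdx)
        expected = {f"f{i}" for i in range(n)
                    if ref[f"f{i}"].std(ddof=0) > 0.01 and cdx[f"f{i}"].std(ddof=0) > 0.01}
        assert set(linked.genes) == expected
        assert len(linked.pairs) == n - len(flat)

    def test_no_retained_pairs_is_an_error(self):
        ref = pd.DataFrame({"A": [1.0, 1.0]})
        cdx = pd.DataFrame({"A": [1.0, 1.0]})
        with pytest.raises(ValueError, match="no linked features"):
            ann.link_features(ref, cdx)


class TestPivots:
    def test_separable_pivots_are_pure(self):
        ref, cdx, labels, truth, alias = two_modality_toy()
        linked = ann.link_features(ref, cdx, alias)
        pivots = ann.match_pivots(ref, cdx, linked, pivot_fraction=0.2, seed=0)
        assert len(pivots.matches) > 0
        transferred = ann.transfer_labels(pivots, labels)
        assert (transferred == truth.reindex(transferred.index)).all()

    def test_zero_smoothing_is_identity_limit(self):
        ref, cdx, labels, truth, alias = two_modality_toy(noise=0.3, seed=1)
        linked = ann.link_features(ref, cdx, alias)
        full = ref[linked.genes].to_numpy(dtype=float)
        smoothed = ann._smooth(full, full, weight=0.0, n_neighbors=5)
        assert smoothed is full  # w = 0 leaves vectors untouched
        p = ann.match_pivots(ref, cdx, linked, smoothing_weight=0.0, seed=0)
        assert len(p.matches) > 0

    def test_pivot_fraction_controls_count(self):
        ref, cdx, labels, truth, alias = two_modality_toy(noise=0.2, seed=2)
        linked = ann.link_features(ref, cdx, alias)
        p_small = ann.match_pivots(ref, cdx, linked, pivot_fraction=0.1, seed=0)
        p_all = ann.match_pivots(ref, cdx, linked, pivot_fraction=1.0, seed=0)
        assert len(p_small.matches) == round(0.1 * len(cdx))
        assert len(p_all.matches) >= len(p_small.matches)
        # scores sorted descending, one match per imaging cell at most
        assert (np.diff(p_all.matches["score"]) <= 1e-12).all()
        assert p_all.matches["cell_id"].is_unique

    def test_deterministic_and_feature_order_invariant(self):
        ref, cdx, labels, truth, alias = two_modality_toy(noise=0.2, seed=3)
        linked = ann.link_features(ref, cdx, alias)
        p1 = ann.match_pivots(ref, cdx, linked, seed=5)
        p2 = ann.match_pivots(ref, cdx, linked, seed=5)
        pd.testing.assert_frame_equal(p1.matches, p2.matches)


class TestTransferAndPropagate:
    def test_transfer_and_permutation_equivariance(self):
        ref, cdx, labels, truth, alias = two_modality_toy()
        linked = ann.link_features(ref, cdx, alias)
        pivots = ann.match_pivots(ref, cdx, linked, seed=0)
        base = ann.transfer_labels(pivots, labels)
        permuted = ann.transfer_labels(pivots, labels.map({"T0": "X", "T1": "Y"}))
        assert (permuted == base.map({"T0": "X", "T1": "Y"})).all()

    def test_missing_reference_label_rejected(self):
        ref, cdx, labels, truth, alias = two_modality_toy()
        linked = ann.link_features(ref, cdx, alias)
        pivots = ann.match_pivots(ref, cdx, linked, seed=0)
        with pytest.raises(ValueError, match="without labels"):
            ann.transfer_labels(pivots, labels.iloc[:1])

    def test_separable_propagation_perfect_f1(self):
        ref, cdx, labels, truth, alias = two_modality_toy()
        pivot_labels = truth.iloc[list(range(10)) + list(range(40, 50))]
        out, metrics = ann.propagate_labels(pivot_labels, cdx, seed=0)
        assert metrics["macro_f1"] == 1.0
        assert (out["label"] == truth).all()

    def test_identical_cell_gets_pivot_class(self):
        ref, cdx, labels, truth, alias = two_modality_toy()
        cdx2 = cdx.copy()
        cdx2.loc["c_clone"] = cdx.loc["c0"]
        pivot_labels = truth.iloc[list(range(10)) + list(range(40, 50))]
        out, _ = ann.propagate_labels(pivot_labels, cdx2, seed=0)
        assert out.loc["c_clone", "label"] == truth.loc["c0"]

    def test_single_class_pivots_rejected(self):
        _, cdx, _, truth, _ = two_modality_toy()
        with pytest.raises(ValueError, match="two classes"):
            ann.propagate_labels(truth.iloc[:5], cdx, seed=0)


def test_accuracy_monotone_in_noise():
    """Pivot purity and propagation accuracy do not improve as imaging noise grows."""
    purities, accuracies = [], []
    for cv in (0.05, 0.4, 1.5):
        t = syn.generate_tissue(n_cells=800, n_types=4, n_genes=60, n_markers=12, seed=17)
        cells = syn.render_codex(t, syn.NoiseConfig(protein_cv=cv), seed=18)
        norm, _ = codex.normalize_features(cells)
        cmat = norm.set_index("cell_id")[codex.marker_columns(norm)]
        ref, ref_labels = syn.sample_reference_profiles(t, 800, 1e4, seed=19)
        refn = np.log1p(ref.div(ref.sum(axis=1), axis=0) * 1e4)
        linked = ann.link_features(refn, cmat, syn.default_alias_map(t))
        pivots = ann.match_pivots(refn, cmat, linked, seed=0)
        transferred = ann.transfer_labels(pivots, ref_labels)
        truth = t.cells.set_index("cell_id")["type"]
        purities.append((transferred == truth.reindex(transferred.index)).mean())
        out, _ = ann.propagate_labels(transferred, cmat, seed=0)
        accuracies.append((out["label"] == truth).mean())
    tol = 0.02  # small non-monotonic wiggle allowed between adjacent levels
    assert purities[0] >= purities[1] - tol >= purities[2] - 2 * tol
    assert accuracies[0] >= accuracies[1] - tol >= accuracies[2] - 2 * tol
    assert purities[0] > 0.95 and accuracies[0] > 0.9
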