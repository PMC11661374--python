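"""Cell-to-spot mapping, proportions, signatures, spot splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spotsplit import deconvolution as dec
from conftest import make_spot_matrix


def cells_at(points):
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(pts))], "x": pts[:, 0], "y": pts[:, 1]})


class TestAssignment:
    def test_cell_at_spot_center(self):
        sm = make_spot_matrix(np.zeros((4, 2)), pixel_size=10.0, origin=(5.0, 5.0))
        a = dec.assign_cells_to_spots(cells_at([[5.0, 5.0]]), sm)
        assert a.iloc[0] == "s0"

    def test_gap_cell_unassigned(self):
        # pitch 20, width 10: midway between two channels is in the dead zone
        sm = make_spot_matrix(np.zeros((4, 2)), pixel_size=10.0, pitch=20.0, origin=(10.0, 10.0))
        a = dec.assign_cells_to_spots(cells_at([[20.0, 10.0]]), sm)
        assert a.iloc[0] is None

    def test_half_open_right_edge_excluded(self):
        sm = make_spot_matrix(np.zeros((4, 2)), pixel_size=10.0, origin=(5.0, 5.0))
        # spot s0 spans [0, 10) x [0, 10); its right edge belongs to s1
        a = dec.assign_cells_to_spots(cells_at([[10.0, 5.0], [9.999, 5.0], [0.0, 0.0]]), sm)
        assert list(a) == ["s1", "s0", "s0"]

    def test_overlapping_footprints_rejected(self):
        sm = make_spot_matrix(np.zeros((4, 2)), pixel_size=10.0, origin=(5.0, 5.0))
        sm.pixel_size = 25.0  # wider than the pitch
        with pytest.raises(ValueError, match="overlap"):
            dec.assign_cells_to_spots(cells_at([[5.0, 5.0]]), sm)

    def test_each_cell_at_most_one_spot(self, rng):
        sm = make_spot_matrix(np.zeros((16, 3)), pixel_size=8.0, pitch=10.0, origin=(5.0, 5.0))
        cells = cells_at(rng.uniform(-5, 50, (300, 2)))
        a = dec.assign_cells_to_spots(cells, sm)
        assert len(a) == 300  # one row per cell, by construction single-valued


class TestProportions:
    def test_examples(self):
        assignment = pd.Series(["s0", "s1", "s1", "s1"], index=["c0", "c1", "c2", "c3"])
        labels = pd.Series(["A", "A", "A", "B"], index=["c0", "c1", "c2", "c3"])
        p = dec.compute_proportions(assignment, labels, ["A", "B"], ["s0", "s1", "s2"])
        assert p.beta.loc["A", "s0"] == 1.0 and p.beta.loc["B", "s0"] == 0.0
        np.testing.assert_allclose(p.beta["s1"], [2 / 3, 1 / 3])
        assert p.empty["s2"] and (p.beta["s2"] == 0).all()

    def test_unlabeled_cell_reported(self):
        assignment = pd.Series(["s0"], index=["c0"])
        labels = pd.Series([], dtype=object)
        with pytest.raises(ValueError, match="c0"):
            dec.compute_proportions(assignment, labels, ["A"], ["s0"])


class TestSignatures:
    def test_mean_and_invariances(self):
        expr = pd.DataFrame([[1.0, 3.0], [3.0, 5.0], [2.0, 2.0]],
                            index=["r0", "r1", "r2"], columns=["g0", "g1"])
        labels = pd.Series(["A", "A", "B"], index=expr.index)
        mu = dec.aggregate_signatures(expr, labels)
        np.testing.assert_allclose(mu.loc["A"], [2.0, 4.0])
        np.testing.assert_allclose(mu.loc["B"], [2.0, 2.0])
        # single profile per type equals that profile; duplication is a no-op
        doubled = dec.aggregate_signatures(pd.concat([expr, expr]), pd.concat([labels, labels]))
        pd.testing.assert_frame_equal(mu, doubled)

    def test_unlabeled_profile_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["r0"], columns=["g0"])
        with pytest.raises(ValueError):
            dec.aggregate_signatures(expr, pd.Series([], dtype=object))


def proportions_from_beta(beta: pd.DataFrame, n_cells=None):
    if n_cells is None:
        n_cells = pd.Series((beta.sum(axis=0) > 0).astype(int) * 3, index=beta.columns)
    return dec.SpotProportionMatrix(beta=beta, n_cells=n_cells)


class TestSplitting:
    def mu2(self):
        return pd.DataFrame([[2.0], [6.0]], index=["A", "B"], columns=["G000"])

    def test_single_type_spot_gets_everything(self):
        sm = make_spot_matrix([[7.0]])
        beta = pd.DataFrame({"s0": [1.0, 0.0]}, index=["A", "B"])
        t = dec.split_spots(sm, proportions_from_beta(beta), self.mu2())
        np.testing.assert_allclose(t.tensor[0, 0], [7.0, 0.0])

    def test_printed_formula(self):
        sm = make_spot_matrix([[10.0]])
        beta = pd.DataFrame({"s0": [0.5, 0.5]}, index=["A", "B"])
        t = dec.split_spots(sm, proportions_from_beta(beta), self.mu2())
        # denominator 0.5*2 + 0.5*6 = 4 -> (10*0.5*2/4, 10*0.5*6/4)
        np.testing.assert_allclose(t.tensor[0, 0], [2.5, 7.5])

    def test_zero_denominator_policies(self):
        sm = make_spot_matrix([[4.0]])
        beta = pd.DataFrame({"s0": [0.5, 0.5]}, index=["A", "B"])
        mu = pd.DataFrame([[0.0], [0.0]], index=["A", "B"], columns=["G000"])
        t_beta = dec.split_spots(sm, proportions_from_beta(beta), mu, "beta")
        np.testing.assert_allclose(t_beta.tensor[0, 0], [2.0, 2.0])
        t_drop = dec.split_spots(sm, proportions_from_beta(beta), mu, "drop")
        np.testing.assert_allclose(t_drop.tensor[0, 0], [0.0, 0.0])
        assert t_drop.unassigned[0, 0] == 4.0

    def test_misaligned_types_rejected(self):
        sm = make_spot_matrix([[1.0]])
        beta = pd.DataFrame({"s0": [1.0]}, index=["Z"])
        with pytest.raises(ValueError, match="absent"):
            dec.split_spots(sm, proportions_from_beta(beta), self.mu2())

    def test_genes_aligned_by_name(self, rng):
        sm = make_spot_matrix(rng.integers(0, 20, (4, 3)).astype(float))  # genes G000..G002
        beta = pd.DataFrame(rng.dirichlet([1, 1], size=4).T, columns=sm.spot_ids, index=["A", "B"])
        mu = pd.DataFrame(rng.uniform(0.1, 1, (2, 2)), index=["A", "B"], columns=["G002", "G001"])
        t = dec.split_spots(sm, proportions_from_beta(beta, pd.Series(1, index=sm.spot_ids)), mu)
        assert t.genes == ["G001", "G002"]  # spot-matrix order, intersected

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_conservation_and_support(self, seed):
        rng = np.random.default_rng(seed)
        n_spots, n_genes, n_types = rng.integers(1, 12), rng.integers(1, 15), rng.integers(1, 5)
        x = rng.integers(0, 50, (n_spots, n_genes)).astype(float)
        sm = make_spot_matrix(x)
        types = [f"T{k}" for k in range(n_types)]
        beta_arr = rng.dirichlet(np.full(n_types, 0.5), size=n_spots).T
        beta_arr[beta_arr < 0.05] = 0.0  # introduce exact zeros
        colsum = beta_arr.sum(axis=0)
        beta_arr = np.divide(beta_arr, colsum, out=np.zeros_like(beta_arr), where=colsum > 0)
        beta = pd.DataFrame(beta_arr, index=types, columns=sm.spot_ids)
        n_cells = pd.Series((colsum > 0).astype(int) * 2, index=sm.spot_ids)
        mu = pd.DataFrame(rng.uniform(0, 1, (n_types, n_genes)) * (rng.random((n_types, n_genes)) > 0.2),
                          index=types, columns=sm.genes)
        if (mu.sum(axis=1) == 0).any():
            mu.iloc[:, 0] += 0.1
        t = dec.split_spots(sm, dec.SpotProportionMatrix(beta=beta, n_cells=n_cells), mu)
        occupied = n_cells.to_numpy() > 0
        totals = t.tensor.sum(axis=2)
        np.testing.assert_allclose(totals[occupied], x[occupied], rtol=1e-9, atol=1e-9)
        assert (totals[~occupied] == 0).all()
        assert (t.tensor >= 0).all()
        # support: no mass on types absent from the spot
        absent = beta_arr.T == 0  # (S, K)
        assert (t.tensor.transpose(0, 2, 1)[absent] == 0).all()

    def test_per_gene_scale_equivariance(self, rng):
        x = rng.integers(0, 30, (5, 4)).astype(float)
        sm = make_spot_matrix(x)
        types = ["A", "B", "C"]
        beta = pd.DataFrame(rng.dirichlet([1, 1, 1], size=5).T, index=types, columns=sm.spot_ids)
        prop = dec.SpotProportionMatrix(beta=beta, n_cells=pd.Series(2, index=sm.spot_ids))
        mu = pd.DataFrame(rng.uniform(0.1, 2, (3, 4)), index=types, columns=sm.genes)
        t1 = dec.split_spots(sm, prop, mu)
        gene_scale = rng.uniform(0.5, 5, 4)
        t2 = dec.split_spots(sm, prop, mu * gene_scale)
        np.testing.assert_allclose(t1.tensor, t2.tensor, rtol=1e-9)

    def test_per_type_scale_matches_reweighted_beta(self, rng):
        x = rng.integers(1, 30, (5, 4)).astype(float)
        sm = make_spot_matrix(x)
        types = ["A", "B"]
        beta = pd.DataFrame(rng.dirichlet([1, 1], size=5).T, index=types, columns=sm.spot_ids)
        prop = dec.SpotProportionMatrix(beta=beta, n_cells=pd.Series(2, index=sm.spot_ids))
        mu = pd.DataFrame(rng.uniform(0.1, 2, (2, 4)), index=types, columns=sm.genes)
        c = np.array([2.0, 0.5])
        t1 = dec.split_spots(sm, prop, mu * c[:, None])
        reweighted = beta * c[:, None]
        reweighted = reweighted / reweighted.sum(axis=0)
        t2 = dec.split_spots(sm, dec.SpotProportionMatrix(beta=reweighted, n_cells=pd.Series(2, index=sm.spot_ids)), mu)
        np.testing.assert_allclose(t1.tensor, t2.tensor, rtol=1e-9)


class TestProteinSubspots:
    def test_mean_aggregation_and_key_match(self):
        cells = pd.DataFrame(
            {"cell_id": ["c0", "c1", "c2"], "x": 0.0, "y": 0.0, "area": 1.0,
             "M00": [0.2, 0.6, 0.9]}
        )
        assignment = pd.Series(["s0", "s0", "s1"], index=["c0", "c1", "c2"])
        labels = pd.Series(["A", "A", "B"], index=["c0", "c1", "c2"])
        agg = dec.aggregate_codex_subspots(cells, assignment, labels)
        assert agg.loc[("s0", "A"), "M00"] == pytest.approx(0.4)
        assert agg.loc[("s1", "B"), "M00"] == pytest.approx(0.9)
        # keys coincide with RNA sub-spot keys from the same assignment
        sm = make_spot_matrix(np.ones((2, 1)))
        prop = dec.compute_proportions(assignment, labels, ["A", "B"], sm.spot_ids)
        mu = pd.DataFrame([[1.0], [1.0]], index=["A", "B"], columns=sm.genes)
        keys, _ = dec.split_spots(sm, prop, mu).flattened()
        rna_keys = set(map(tuple, keys.to_numpy()))
        assert rna_keys == set(agg.index)
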