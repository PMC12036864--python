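"""Anchored deconvolution: exact recovery, constraints and marker discovery."""

import numpy as np
import pandas as pd
import pytest

from cellcomm.deconv import AnchorSet, fit_deconvolution, marker_specificity
from cellcomm.deconv import _project_simplex_columns
from cellcomm.evaluate import match_components_by_proportions, proportion_mae
from cellcomm.io import ExpressionMatrix, FormatError


def _planted_fixture(seed=0, G=50, K=2, n=20):
    """X built exactly as S0 @ P0 with disjoint anchors, no noise."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(G)]
    cells = [f"c{k}" for k in range(K)]
    S = rng.lognormal(np.log(50), 0.8, size=(G, K))
    anchors = {}
    for k in range(K):
        rows = range(k * 5, k * 5 + 5)
        anchors[cells[k]] = frozenset(genes[i] for i in rows)
        for i in rows:
            S[i, :] = 0.0
            S[i, k] = 500.0
    S = S / S.sum(axis=0, keepdims=True) * 1e6
    raw = rng.dirichlet(np.ones(K), size=n).T
    P = raw / raw.sum(axis=0, keepdims=True)
    X = S @ P
    mat = ExpressionMatrix(genes, [f"s{j}" for j in range(n)], X / X.sum(axis=0) * 1e6, "cpm")
    return mat, AnchorSet(anchors), pd.DataFrame(S, index=genes, columns=cells), pd.DataFrame(
        P, index=cells, columns=mat.sample_ids
    )


class TestSimplexProjection:
    def test_columns_on_simplex(self, rng):
        V = rng.normal(size=(5, 30))
        P = _project_simplex_columns(V)
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_identity_on_simplex_points(self, rng):
        V = rng.dirichlet(np.ones(4), size=10).T
        np.testing.assert_allclose(_project_simplex_columns(V), V, atol=1e-12)


class TestFitDeconvolution:
    def test_exact_recovery_planted(self):
        mat, anchors, S0, P0 = _planted_fixture()
        res = fit_deconvolution(mat, anchors, seed=0)
        est = res.proportions.loc[P0.index, P0.columns].to_numpy()
        assert np.abs(est - P0.to_numpy()).max() < 1e-3

    def test_pure_sample_is_one_hot(self):
        mat, anchors, S0, P0 = _planted_fixture()
        pure = S0.to_numpy()[:, [0]] * 3.0
        mat2 = ExpressionMatrix(
            mat.gene_ids, ["pure"], pure / pure.sum() * 1e6, "cpm"
        )
        res = fit_deconvolution(mat2, anchors, seed=0)
        p = res.proportions["pure"]
        assert p["c0"] == pytest.approx(1.0, abs=1e-3)
        assert p["c1"] == pytest.approx(0.0, abs=1e-3)

    def test_gene_permutation_symmetry(self, rng):
        mat, anchors, *_ = _planted_fixture()
        perm = rng.permutation(mat.n_genes)
        mat_p = ExpressionMatrix(
            [mat.gene_ids[i] for i in perm], mat.sample_ids, mat.values[perm], "cpm"
        )
        res_a = fit_deconvolution(mat, anchors, seed=0)
        res_b = fit_deconvolution(mat_p, anchors, seed=0)
        np.testing.assert_allclose(
            res_a.proportions.to_numpy(), res_b.proportions.to_numpy(), atol=1e-9
        )

    def test_objective_trace_non_increasing(self):
        mat, anchors, *_ = _planted_fixture(seed=3)
        res = fit_deconvolution(mat, anchors, seed=1)
        tr = res.objective_trace
        assert all(b <= a * (1 + 1e-12) for a, b in zip(tr, tr[1:]))

    def test_proportions_on_simplex(self):
        mat, anchors, *_ = _planted_fixture(seed=5)
        res = fit_deconvolution(mat, anchors, seed=0)
        P = res.proportions.to_numpy()
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-8)
        assert (P >= 0).all()

    def test_anchor_rows_hard_zeroed(self):
        mat, anchors, *_ = _planted_fixture()
        res = fit_deconvolution(mat, anchors, seed=0)
        for gene, cell in res.anchor_types.items():
            row = res.signatures.loc[gene]
            off = row.drop(cell)
            assert (off == 0).all()

    def test_anchor_order_permutation_permutes_P(self):
        mat, anchors, *_ = _planted_fixture()
        rev = AnchorSet(dict(reversed(list(anchors.anchors.items()))))
        res_a = fit_deconvolution(mat, anchors, seed=0)
        res_b = fit_deconvolution(mat, rev, seed=0)
        np.testing.assert_allclose(
            res_a.proportions.loc[["c0", "c1"]].to_numpy(),
            res_b.proportions.loc[["c0", "c1"]].to_numpy(),
            atol=1e-6,
        )

    def test_missing_anchor_warns_all_missing_raises(self):
        mat, anchors, *_ = _planted_fixture()
        with_extra = {k: v | {f"absent_{k}"} for k, v in anchors.anchors.items()}
        with pytest.warns(UserWarning, match="absent"):
            fit_deconvolution(mat, AnchorSet(with_extra), seed=0)
        bad = AnchorSet({"c0": frozenset(["nope"]), "c1": anchors.anchors["c1"]})
        with pytest.raises(FormatError, match="c0"):
            fit_deconvolution(mat, bad, seed=0)

    def test_wrong_unit_rejected(self, small_counts):
        with pytest.raises(FormatError):
            fit_deconvolution(small_counts, AnchorSet({"a": frozenset(["g1"]),
                                                       "b": frozenset(["g2"])}), seed=0)


class TestMarkerSpecificity:
    def _res_with_signatures(self, S, cells):
        genes = [f"g{i}" for i in range(S.shape[0])]
        from cellcomm.deconv import DeconvResult

        return DeconvResult(
            signatures=pd.DataFrame(S, index=genes, columns=cells),
            proportions=pd.DataFrame(
                np.full((len(cells), 2), 1 / len(cells)), index=cells, columns=["s1", "s2"]
            ),
            objective_trace=[1.0],
            restarts_used=1,
            seed=0,
            converged=True,
        )

    def test_specificity_arithmetic(self):
        res = self._res_with_signatures(np.array([[90.0, 10.0]]), ["a", "b"])
        res = marker_specificity(res, min_signature=10, spec_min=0.7)
        assert res.markers["a"] == [("g0", pytest.approx(0.9))]
        assert res.markers["b"] == []

    def test_flat_row_never_marker(self):
        res = self._res_with_signatures(np.full((1, 4), 50.0), list("abcd"))
        res = marker_specificity(res, spec_min=0.7)
        assert all(not v for v in res.markers.values())

    def test_low_signal_rows_excluded(self):
        res = self._res_with_signatures(np.array([[9.0, 0.1]]), ["a", "b"])
        res = marker_specificity(res, min_signature=10)
        assert res.markers["a"] == []

    def test_sorted_by_specificity_then_name(self):
        S = np.array([[80.0, 20.0], [95.0, 5.0], [80.0, 20.0]])
        res = self._res_with_signatures(S, ["a", "b"])
        res = marker_specificity(res)
        assert [g for g, _ in res.markers["a"]] == ["g1", "g0", "g2"]


class TestAnchorSetValidation:
    def test_overlapping_anchor_sets_rejected(self):
        with pytest.raises(FormatError, match="shared"):
            AnchorSet({"a": frozenset(["g1"]), "b": frozenset(["g1", "g2"])})

    def test_empty_set_rejected(self):
        with pytest.raises(FormatError):
            AnchorSet({"a": frozenset()})

    def test_cell_names_include_free(self):
        a = AnchorSet({"x": frozenset(["g1"])}, k_free=2)
        assert a.cell_names == ["x", "free_1", "free_2"]
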