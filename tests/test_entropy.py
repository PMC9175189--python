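"""Closed-form and oracle checks for the entropy decomposition."""

import numpy as np
import pandas as pd
import pytest

import ientropy as ie
from ientropy.entropy import (
    GAUSSIAN_UNIT_ENTROPY,
    NotPositiveDefiniteError,
    intrinsic_entropy,
)

from conftest import make_correlated_gene_fixture


def _expr(values, seed_ids=None):
    values = np.asarray(values, dtype=float)
    genes = np.array([f"g{i}" for i in range(values.shape[0])], dtype=object)
    cells = np.array([f"c{i}" for i in range(values.shape[1])], dtype=object)
    return ie.ExprMatrix(values, genes, cells)


class TestGaussianEntropy:
    def test_standard_normal(self):
        assert ie.gaussian_entropy(1.0) == pytest.approx(
            0.5 * np.log(2 * np.pi * np.e), abs=1e-10
        )
        assert ie.gaussian_entropy(1.0) == pytest.approx(1.4189385, abs=1e-6)

    def test_additivity_identity_2d(self):
        assert ie.gaussian_entropy(np.eye(2)) == pytest.approx(
            np.log(2 * np.pi * np.e), abs=1e-10
        )

    def test_correlated_pair(self):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        expected = np.log(2 * np.pi * np.e) + 0.5 * np.log(0.36)
        assert ie.gaussian_entropy(cov) == pytest.approx(expected, abs=1e-10)

    def test_scaling_shifts_by_log_det(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.5]])
        h = ie.gaussian_entropy(cov)
        assert ie.gaussian_entropy(4.0 * cov) == pytest.approx(
            h + 2 * np.log(2.0), abs=1e-10
        )

    def test_rejects_asymmetric_and_indefinite(self):
        with pytest.raises(ValueError, match="symmetric"):
            ie.gaussian_entropy(np.array([[1.0, 0.5], [0.1, 1.0]]))
        with pytest.raises(NotPositiveDefiniteError):
            ie.gaussian_entropy(np.array([[1.0, 0.0], [0.0, -0.5]]))

    def test_monte_carlo_resubstitution_small(self):
        # resubstitution estimate -E[ln p(X)] on exact Gaussian samples
        rng = np.random.default_rng(0)
        a = rng.normal(size=(3, 3))
        cov = a @ a.T + 0.5 * np.eye(3)
        draws = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        inv = np.linalg.inv(cov)
        _, logdet = np.linalg.slogdet(cov)
        logp = -0.5 * (
            np.einsum("ij,jk,ik->i", draws, inv, draws)
            + 3 * np.log(2 * np.pi) + logdet
        )
        assert ie.gaussian_entropy(cov) == pytest.approx(-logp.mean(), abs=1e-2)


class TestComputePCs:
    def test_shape_contract(self, scored_expr):
        expr, pcs, _, _ = scored_expr
        assert pcs.scores.shape == (expr.n_cells, 20)

    def test_rank_one_data(self):
        rng = np.random.default_rng(3)
        pattern = rng.normal(size=40)
        weights = rng.normal(size=15)
        expr = _expr(np.outer(weights, pattern))
        pcs = ie.compute_pcs(expr, n_pcs=1)
        total_var = expr.values.var(axis=1, ddof=1).sum()
        assert pcs.explained_variance[0] == pytest.approx(total_var, abs=1e-8)

    def test_low_rank_roundtrip(self):
        # rank-8 planted structure: 10 components reconstruct it exactly
        rng = np.random.default_rng(5)
        expr = _expr(rng.normal(size=(20, 8)) @ rng.normal(size=(8, 30)))
        pcs = ie.compute_pcs(expr, n_pcs=10)
        centered = (expr.values - expr.values.mean(axis=1, keepdims=True)).T
        np.testing.assert_allclose(pcs.scores @ pcs.loadings, centered, atol=1e-8)

    def test_loadings_orthonormal(self, scored_expr):
        _, pcs, _, _ = scored_expr
        gram = pcs.loadings @ pcs.loadings.T
        np.testing.assert_allclose(gram, np.eye(pcs.n_pcs), atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(6)
        expr = _expr(rng.normal(size=(12, 25)))
        a = ie.compute_pcs(expr, n_pcs=5)
        b = ie.compute_pcs(expr, n_pcs=5)
        np.testing.assert_array_equal(a.scores, b.scores)
        idx = np.argmax(np.abs(a.loadings), axis=1)
        assert (a.loadings[np.arange(5), idx] > 0).all()

    def test_n_pcs_over_rank_errors(self):
        expr = _expr(np.random.default_rng(7).normal(size=(4, 6)))
        with pytest.raises(ValueError, match="attainable maximum 3"):
            ie.compute_pcs(expr, n_pcs=4)


class TestTotalEntropy:
    def test_unit_and_scaled_variance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=100)
        x = (x - x.mean()) / x.std(ddof=1)
        expr = _expr(np.vstack([x, 2.0 * x + 1.0]))
        te = ie.total_entropy(expr)
        assert te[0] == pytest.approx(1.4189385, abs=1e-6)
        # variance 4 -> +0.5 ln 4; also equals gaussian_entropy of the 1x1 cov
        assert te[1] == pytest.approx(1.4189385 + 0.5 * np.log(4), abs=1e-6)
        assert te[1] == pytest.approx(ie.gaussian_entropy(np.array([[4.0]])), abs=1e-10)

    def test_scaling_property(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        expr = _expr(np.vstack([x, 5.0 * x]))
        te = ie.total_entropy(expr)
        assert te[1] - te[0] == pytest.approx(np.log(5.0), abs=1e-10)

    def test_zero_variance_is_nan(self):
        te = ie.total_entropy(_expr(np.vstack([np.ones(10), np.arange(10.0)])))
        assert np.isnan(te[0]) and np.isfinite(te[1])


class TestIntrinsicEntropy:
    def test_independent_gene_has_zero_ee(self):
        expr, pcs = make_correlated_gene_fixture(rho=0.0)
        row = ie.intrinsic_entropy(expr, pcs).iloc[0]
        assert row["ee"] == pytest.approx(0.0, abs=1e-10)
        assert row["ie"] == pytest.approx(row["te"], abs=1e-10)

    @pytest.mark.parametrize("rho", [0.5, 0.8, 0.95])
    def test_bivariate_mi_closed_form(self, rho):
        expr, pcs = make_correlated_gene_fixture(rho=rho)
        row = ie.intrinsic_entropy(expr, pcs).iloc[0]
        expected_ee = -0.5 * np.log(1.0 - rho**2)
        assert row["ee"] == pytest.approx(expected_ee, abs=1e-6)
        assert row["ie"] == pytest.approx(row["te"] - expected_ee, abs=1e-6)

    def test_rho_08_reference_values(self):
        expr, pcs = make_correlated_gene_fixture(rho=0.8)
        row = ie.intrinsic_entropy(expr, pcs).iloc[0]
        # unit sample variance: TE = 1.4189, IE = 1.4189 + 0.5 ln 0.36
        assert row["te"] == pytest.approx(1.4189385, abs=1e-6)
        assert row["ie"] == pytest.approx(0.9081, abs=1e-4)
        assert row["ee"] == pytest.approx(0.5108, abs=1e-4)

    def test_schur_equals_determinant_ratio(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n_cells = int(rng.integers(12, 51))
            n_genes = int(rng.integers(6, 15))
            n_pcs = int(rng.integers(1, 6))
            expr = _expr(rng.normal(size=(n_genes, n_cells)))
            pcs = ie.compute_pcs(expr, n_pcs=n_pcs)
            a = ie.intrinsic_entropy(expr, pcs, method="schur")
            b = ie.intrinsic_entropy(expr, pcs, method="det")
            np.testing.assert_allclose(a["ie"], b["ie"], atol=1e-8)
            np.testing.assert_allclose(a["te"], b["te"], atol=1e-8)

    def test_matches_joint_entropy_difference(self):
        # IE = H(x, Z) - H(Z) with both joint entropies evaluated on the
        # empirical covariance blocks (the defining identity)
        rng = np.random.default_rng(11)
        expr = _expr(rng.normal(size=(8, 40)))
        pcs = ie.compute_pcs(expr, n_pcs=3)
        table = ie.intrinsic_entropy(expr, pcs).set_index("gene_id")
        zc = pcs.scores - pcs.scores.mean(axis=0)
        cov_z = zc.T @ zc / (expr.n_cells - 1)
        h_z = ie.gaussian_entropy(cov_z)
        for g, row in zip(expr.gene_ids, expr.values):
            xc = row - row.mean()
            joint = np.empty((4, 4))
            joint[0, 0] = xc @ xc / (expr.n_cells - 1)
            joint[0, 1:] = joint[1:, 0] = xc @ zc / (expr.n_cells - 1)
            joint[1:, 1:] = cov_z
            expected = ie.gaussian_entropy(joint) - h_z
            assert table.loc[g, "ie"] == pytest.approx(expected, abs=1e-8)

    def test_decomposition_identity_and_bounds(self, scored_expr):
        _, _, table, _ = scored_expr
        scored = table[~table["degenerate"]]
        np.testing.assert_allclose(
            scored["te"], scored["ie"] + scored["ee"], atol=1e-8
        )
        assert (scored["ee"] >= -1e-8).all()
        assert (scored["ie"] <= scored["te"] + 1e-8).all()

    def test_rank_is_permutation_sorted_by_ie(self, scored_expr):
        _, _, table, _ = scored_expr
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))
        scored = table[~table["degenerate"]]
        assert (np.diff(scored["ie"].to_numpy()) <= 1e-12).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        expr = _expr(rng.normal(size=(15, 30)))
        perm = rng.permutation(30)
        shuffled = ie.ExprMatrix(
            expr.values[:, perm], expr.gene_ids, expr.cell_ids[perm]
        )
        a = ie.intrinsic_entropy(expr, ie.compute_pcs(expr, 4)).set_index("gene_id")
        b = ie.intrinsic_entropy(shuffled, ie.compute_pcs(shuffled, 4)).set_index("gene_id")
        for col in ("te", "ie", "ee"):
            np.testing.assert_allclose(a[col], b.loc[a.index, col], atol=1e-10)

    def test_zero_variance_gene_flagged_degenerate(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=(5, 25))
        values[2] = 3.14
        expr = _expr(values)
        table = ie.intrinsic_entropy(expr, ie.compute_pcs(expr, 2))
        row = table.set_index("gene_id").loc["g2"]
        assert bool(row["degenerate"]) and np.isnan(row["ie"])
        assert row["rank"] == len(table)  # ranked after all scored genes

    def test_mismatched_cells_error(self):
        expr, pcs = make_correlated_gene_fixture(rho=0.5)
        bad = ie.PCEmbedding(
            pcs.scores, pcs.n_pcs, pcs.explained_variance,
            pcs.centering_record, pcs.cell_ids[::-1].copy(), pcs.loadings,
        )
        with pytest.raises(ValueError, match="same cells"):
            ie.intrinsic_entropy(expr, bad)

    def test_leave_one_out_variant_contract(self):
        # the exact per-gene environment obeys the same decomposition and
        # ranking contracts; it sits above the shared-embedding IE because
        # a gene no longer helps predict itself through its own loadings
        rng = np.random.default_rng(14)
        expr = _expr(rng.normal(size=(12, 30)))
        shared = ie.intrinsic_entropy(expr, ie.compute_pcs(expr, 3)).set_index("gene_id")
        loo = ie.intrinsic_entropy_loo(expr, n_pcs=3)
        assert sorted(loo["rank"]) == list(range(1, 13))
        np.testing.assert_allclose(loo["te"], loo["ie"] + loo["ee"], atol=1e-8)
        loo = loo.set_index("gene_id")
        assert (loo.loc[shared.index, "ie"] >= shared["ie"] - 1e-8).all()


def test_extrinsic_entropy_matches_column(scored_expr):
    _, _, table, _ = scored_expr
    pd.testing.assert_series_equal(
        ie.extrinsic_entropy(table), table["ee"], check_names=False
    )
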