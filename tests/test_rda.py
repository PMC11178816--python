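"""Standardization, RDA core, sign convention and variation partitioning."""

import subprocess
import shutil

import numpy as np
import pandas as pd
import pytest

from conftest import partial_rda_oracle, rda_oracle
from structdhi.rda import (
    adjusted_r2,
    fit_partial_rda,
    fit_rda,
    normalize_signs,
    transform_standardize,
    variation_partition,
)


class TestTransformStandardize:
    def test_ln_then_zscore_oracle(self):
        """Column (1, e-1, e^2-1) with offset 1 -> ln values (ln2, 1, 2)."""
        col = np.array([1.0, np.e - 1.0, np.e**2 - 1.0])
        table = pd.DataFrame({"v": col})
        out = transform_standardize(table)
        ln = np.array([np.log(2.0), 1.0, 2.0])
        expected = (ln - ln.mean()) / ln.std(ddof=1)
        np.testing.assert_allclose(out.values["v"], expected, atol=1e-12)

    def test_self_standardization_moments(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.lognormal(size=(200, 3)), columns=list("abc"))
        out = transform_standardize(table)
        np.testing.assert_allclose(out.values.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(ddof=1), 1.0, atol=1e-10)

    def test_constant_column_raises_with_name(self):
        table = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="flat"):
            transform_standardize(table)

    def test_reference_stats_leave_subset_off_centre(self):
        """A stratum standardized with full-sample stats keeps nonzero means."""
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"v": rng.lognormal(size=500)})
        full = transform_standardize(table)
        subset = table.nlargest(100, "v")
        out = transform_standardize(subset, reference=full.record)
        assert abs(out.values["v"].mean()) > 0.5

    def test_nonpositive_rows_dropped_and_counted(self, caplog):
        table = pd.DataFrame({"v": [-2.0, 1.0, 2.0, 3.0]})
        with caplog.at_level("WARNING"):
            out = transform_standardize(table)
        assert out.n_dropped == 1
        assert len(out.values) == 3


class TestRdaCore:
    def test_self_prediction_r2_one(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        m = fit_rda(pd.DataFrame(X.copy()), pd.DataFrame(X))
        assert abs(m.r2_ - 1.0) < 1e-10

    def test_orthogonal_responses_r2_zero(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 4))
        Y0 = rng.standard_normal((50, 2))
        Xc = X - X.mean(0)
        resid = Y0 - Xc @ np.linalg.lstsq(Xc, Y0 - Y0.mean(0), rcond=None)[0]
        m = fit_rda(pd.DataFrame(resid), pd.DataFrame(X))
        assert m.r2_ < 1e-10

    def test_eigenvalues_match_hat_matrix_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 6))
        Y = rng.standard_normal((50, 3)) + X[:, :3]
        m = fit_rda(pd.DataFrame(Y), pd.DataFrame(X))
        eig, r2 = rda_oracle(X, Y)
        np.testing.assert_allclose(m.eigenvalues_, eig, atol=1e-8)
        assert m.r2_ == pytest.approx(r2, abs=1e-10)

    def test_site_scores_orthogonal(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 5))
        Y = rng.standard_normal((60, 3)) + 0.5 * X[:, :3]
        m = fit_rda(pd.DataFrame(Y), pd.DataFrame(X))
        G = m.site_scores_.T @ m.site_scores_
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_loadings_bounded(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 3)) + X[:, :3]
        m = fit_rda(pd.DataFrame(Y), pd.DataFrame(X))
        assert (m.predictor_loadings_.abs() <= 1.0).all().all()
        assert (m.response_loadings_.abs() <= 1.0).all().all()

    def test_single_predictor_closed_form(self):
        """With one predictor, R^2 = mean squared simple correlation."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal(300)
        Y = np.column_stack([0.8 * x, -0.3 * x, np.zeros(300)])
        Y += rng.standard_normal(Y.shape)
        Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        m = fit_rda(pd.DataFrame(Ys), pd.DataFrame({"x": x}))
        r = [np.corrcoef(x, Ys[:, j])[0, 1] for j in range(3)]
        assert m.r2_ == pytest.approx(np.mean(np.square(r)), abs=1e-10)

    def test_sample_size_floor(self):
        X = np.random.default_rng(8).standard_normal((9, 6))
        with pytest.raises(ValueError, match="n > p \\+ q \\+ 1"):
            fit_rda(pd.DataFrame(X[:, :2]), pd.DataFrame(X))

    def test_rank_deficient_predictors_handled(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 3))
        Xdup = np.hstack([X, X[:, :1]])  # exact collinearity
        Y = rng.standard_normal((50, 2)) + X[:, :2]
        m = fit_rda(pd.DataFrame(Y), pd.DataFrame(Xdup))
        eig, r2 = rda_oracle(Xdup, Y)
        assert m.r2_ == pytest.approx(r2, abs=1e-8)


class TestPartialRda:
    def test_empty_covariates_equals_plain(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((40, 4)))
        Y = pd.DataFrame(rng.standard_normal((40, 2)))
        a = fit_rda(Y, X)
        b = fit_partial_rda(Y, X, pd.DataFrame(index=Y.index))
        np.testing.assert_allclose(a.eigenvalues_, b.eigenvalues_, atol=1e-12)

    def test_predictors_in_covariate_span_give_zero(self):
        rng = np.random.default_rng(11)
        W = rng.standard_normal((50, 3))
        X = W @ rng.standard_normal((3, 2))  # X subset of span(W)
        Y = rng.standard_normal((50, 2))
        m = fit_partial_rda(
            pd.DataFrame(Y), pd.DataFrame(X, columns=["x0", "x1"]),
            pd.DataFrame(W, columns=["w0", "w1", "w2"]),
        )
        assert m.r2_ < 1e-10

    def test_matches_two_stage_projection_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((45, 4))
        W = rng.standard_normal((45, 2))
        Y = rng.standard_normal((45, 3))
        Y[:, :2] += X[:, :2] + 0.5 * W
        m = fit_partial_rda(
            pd.DataFrame(Y), pd.DataFrame(X, columns=[f"x{i}" for i in range(4)]),
            pd.DataFrame(W, columns=["w0", "w1"]),
        )
        eig, r2 = partial_rda_oracle(X, Y, W)
        np.testing.assert_allclose(m.eigenvalues_, eig, atol=1e-8)
        assert m.r2_ == pytest.approx(r2, abs=1e-8)

    def test_proportions_relative_to_original_variance(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((60, 3))
        W = rng.standard_normal((60, 2))
        Y = rng.standard_normal((60, 2)) + X[:, :2] + W
        orig = fit_partial_rda(pd.DataFrame(Y), pd.DataFrame(X, columns=list("abc")),
                               pd.DataFrame(W, columns=list("de")))
        cond = fit_partial_rda(pd.DataFrame(Y), pd.DataFrame(X, columns=list("abc")),
                               pd.DataFrame(W, columns=list("de")),
                               proportion_basis="conditional")
        assert orig.r2_ < cond.r2_  # conditioning removes variance from the basis


class TestNormalizeSigns:
    def _model_with_loadings(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.standard_normal((60, 4)),
                         columns=[f"x{i}" for i in range(4)])
        Y = pd.DataFrame(
            rng.standard_normal((60, 3)) + X.iloc[:, :3].to_numpy(),
            columns=["dhi_cum", "dhi_min", "dhi_var"],
        )
        return fit_rda(Y, X)

    def test_cumulative_loading_nonnegative_after(self):
        m = normalize_signs(self._model_with_loadings())
        assert (m.response_loadings_.loc["dhi_cum"] >= 0).all()

    def test_flip_negates_whole_axis(self):
        m = self._model_with_loadings()
        before_pred = m.predictor_loadings_.copy()
        before_resp = m.response_loadings_.copy()
        flips = before_resp.loc["dhi_cum"].to_numpy() < 0
        normalize_signs(m)
        sign = np.where(flips, -1.0, 1.0)
        np.testing.assert_allclose(m.predictor_loadings_, before_pred * sign)
        np.testing.assert_allclose(m.response_loadings_, before_resp * sign)

    def test_positive_axis_untouched_and_idempotent(self):
        m = normalize_signs(self._model_with_loadings())
        once = m.response_loadings_.copy()
        eig = m.eigenvalues_.copy()
        normalize_signs(m)
        np.testing.assert_array_equal(m.response_loadings_, once)
        np.testing.assert_array_equal(m.eigenvalues_, eig)

    def test_missing_designated_column_raises(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.standard_normal((40, 3)))
        Y = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"])
        m = fit_rda(Y, X)
        with pytest.raises(ValueError, match="dhi_cum"):
            normalize_signs(m)


class TestVariationPartition:
    def test_duplicated_set_all_shared(self):
        rng = np.random.default_rng(16)
        X1 = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        X2 = X1.copy()
        X2.columns = ["a2", "b2", "c2"]
        Y = pd.DataFrame(rng.standard_normal((60, 2)) + X1.to_numpy()[:, :2])
        vp = variation_partition(Y, X1, X2)
        assert abs(vp.a) < 1e-10 and abs(vp.c) < 1e-10
        assert vp.b == pytest.approx(vp.r2_x1, abs=1e-10)

    def test_orthogonal_design_no_overlap(self):
        rng = np.random.default_rng(17)
        M = rng.standard_normal((64, 6))
        Q, _ = np.linalg.qr(M - M.mean(0))  # orthonormal AND mean-zero columns
        X1 = pd.DataFrame(Q[:, :2], columns=["p1", "p2"])
        X2 = pd.DataFrame(Q[:, 2:4], columns=["m1", "m2"])
        E = Q[:, 4:]
        Y = pd.DataFrame(X1.to_numpy() @ np.diag([1.0, 0.5]) + 0.7 * X2.to_numpy() + E)
        vp = variation_partition(Y, X1, X2)
        assert abs(vp.b) < 1e-8
        assert vp.a == pytest.approx(vp.r2_x1, abs=1e-8)
        assert vp.c == pytest.approx(vp.r2_x2, abs=1e-8)

    def test_overlapping_names_rejected(self):
        rng = np.random.default_rng(18)
        X1 = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        X2 = pd.DataFrame(rng.standard_normal((30, 2)), columns=["b", "c"])
        Y = pd.DataFrame(rng.standard_normal((30, 2)))
        with pytest.raises(ValueError, match="share column names"):
            variation_partition(Y, X1, X2)

    def test_fraction_identities_random_instances(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            n = int(rng.integers(30, 80))
            X1 = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
            X2 = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("def"))
            Y = pd.DataFrame(
                rng.standard_normal((n, 2))
                + X1.to_numpy()[:, :2] * rng.normal()
                + X2.to_numpy()[:, :2] * rng.normal()
            )
            vp = variation_partition(Y, X1, X2)
            assert vp.a + vp.b + vp.c == pytest.approx(vp.r2_full, abs=1e-10)
            assert vp.a + vp.b == pytest.approx(vp.r2_x1, abs=1e-10)
            assert vp.b + vp.c == pytest.approx(vp.r2_x2, abs=1e-10)
            assert vp.residual == pytest.approx(1 - vp.r2_full, abs=1e-12)

    def test_fractions_match_projection_oracle(self):
        rng = np.random.default_rng(20)
        X1 = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        X2 = pd.DataFrame(rng.standard_normal((50, 2)), columns=list("de"))
        Y = pd.DataFrame(rng.standard_normal((50, 3)) + X1.to_numpy())
        vp = variation_partition(Y, X1, X2)
        _, r1 = rda_oracle(X1.to_numpy(), Y.to_numpy())
        _, r2 = rda_oracle(X2.to_numpy(), Y.to_numpy())
        _, rf = rda_oracle(np.hstack([X1, X2]), Y.to_numpy())
        assert vp.a == pytest.approx(rf - r2, abs=1e-10)
        assert vp.c == pytest.approx(rf - r1, abs=1e-10)
        assert vp.b == pytest.approx(r1 + r2 - rf, abs=1e-10)

    def test_adjusted_r2_formula(self):
        assert adjusted_r2(0.5, 101, 5) == pytest.approx(1 - 0.5 * 100 / 95)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestVeganCrossCheck:
    def test_eigenvalues_match_vegan(self, tmp_path):
        """Independent cross-check of plain and partial RDA against R vegan."""
        rng = np.random.default_rng(42)
        X = rng.standard_normal((30, 4))
        Y = rng.standard_normal((30, 2)) + X[:, :2] * 0.8
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        script = f"""
        suppressMessages(library(vegan))
        X <- as.matrix(read.csv('{tmp_path}/X.csv', header=FALSE))
        Y <- as.matrix(read.csv('{tmp_path}/Y.csv', header=FALSE))
        m <- rda(Y ~ X)
        mp <- rda(Y ~ X[,1:2] + Condition(X[,3:4]))
        cat(m$CCA$eig, sum(m$CCA$eig)/m$tot.chi,
            mp$CCA$eig, sum(mp$CCA$eig)/mp$tot.chi, sep='\\n')
        """
        out = subprocess.run(["Rscript", "-"], input=script, text=True,
                             capture_output=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        m = fit_rda(pd.DataFrame(Y), pd.DataFrame(X))
        np.testing.assert_allclose(m.eigenvalues_, vals[:2], rtol=1e-6)
        assert m.r2_ == pytest.approx(vals[2], rel=1e-6)
        mp = fit_partial_rda(
            pd.DataFrame(Y, columns=["y0", "y1"]),
            pd.DataFrame(X[:, :2], columns=["x0", "x1"]),
            pd.DataFrame(X[:, 2:], columns=["w0", "w1"]),
        )
        np.testing.assert_allclose(mp.eigenvalues_, vals[3:5], rtol=1e-6)
        assert mp.r2_ == pytest.approx(vals[5], rel=1e-6)
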