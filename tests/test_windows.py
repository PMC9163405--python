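"""Tests of tapered windows, weighted covariance, glasso and residualization."""

import numpy as np
import pandas as pd
import pytest

from dynfc.simulate import TimeCourseMatrix
from dynfc.windows import (GlassoConfig, TaperedWindowSpec, WindowedFCStack,
                           dynamic_fc, edge_index, fisher_z, graphical_lasso,
                           make_tapered_windows, matrix_to_vec,
                           residualize_covariates, select_penalty, static_fc,
                           vec_to_matrix, weighted_window_covariance)


def _tc(data, sid="s1", tr=2.0):
    labels = [f"net{i+1}" for i in range(data.shape[1])]
    return TimeCourseMatrix(sid, labels, np.asarray(data, float), tr)


class TestWindowSpec:
    def test_default_window_count_170(self):
        assert TaperedWindowSpec().n_windows(170) == 148

    @pytest.mark.parametrize("w,expected", [(20, 150), (30, 140)])
    def test_alternate_window_lengths(self, w, expected):
        assert TaperedWindowSpec(window_length_tr=w).n_windows(170) == expected

    def test_plus_one_convention(self):
        spec = TaperedWindowSpec(count_convention="n_minus_w_plus_1")
        assert spec.n_windows(170) == 149

    def test_step_two_halves_count(self):
        assert TaperedWindowSpec(step_tr=2).n_windows(170) == 74

    def test_duration_44s(self):
        assert TaperedWindowSpec().duration_s(2.0) == 44.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            TaperedWindowSpec().n_windows(22)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TaperedWindowSpec(window_length_tr=2)
        with pytest.raises(ValueError):
            TaperedWindowSpec(taper_sigma_tr=0.0)
        with pytest.raises(ValueError):
            TaperedWindowSpec(step_tr=0)
        with pytest.raises(ValueError):
            TaperedWindowSpec(count_convention="bogus")


class TestTaper:
    def test_weights_normalized_symmetric_positive(self):
        w, _ = make_tapered_windows(170, TaperedWindowSpec())
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)
        assert np.all(w > 0)
        # tapered: edges carry less weight than the center
        assert w[0] < w[len(w) // 2]

    def test_tiny_sigma_approaches_rectangle(self):
        w, _ = make_tapered_windows(170, TaperedWindowSpec(taper_sigma_tr=0.01))
        np.testing.assert_allclose(w, np.full(22, 1 / 22), atol=1e-3)

    def test_placements_cover_series(self):
        spec = TaperedWindowSpec()
        _, placements = make_tapered_windows(170, spec)
        assert len(placements) == 148
        assert placements[0] == slice(0, 22)
        assert placements[-1].stop <= 170
        assert all(p.stop - p.start == 22 for p in placements)


class TestFisherZ:
    def test_known_value(self):
        assert fisher_z(np.array(0.5)) == pytest.approx(0.5493061443, abs=1e-9)

    def test_odd_and_monotone(self):
        r = np.linspace(-0.99, 0.99, 41)
        z = fisher_z(r)
        np.testing.assert_allclose(z, -fisher_z(-r), atol=1e-12)
        assert np.all(np.diff(z) > 0)

    def test_r_of_one_clipped_finite(self):
        z = fisher_z(np.array([1.0, -1.0]))
        assert np.all(np.isfinite(z))
        assert z[0] == pytest.approx(np.arctanh(1 - 1e-7))


class TestEdgeVectorization:
    def test_edge_index_order(self):
        assert edge_index(4) == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((6, 6))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        v = matrix_to_vec(m)
        assert v.size == 15
        np.testing.assert_array_equal(vec_to_matrix(v, 6), m)


class TestWeightedCovariance:
    def test_uniform_weights_match_population_covariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((22, 5))
        w = np.full(22, 1 / 22)
        cov = weighted_window_covariance(x, w, slice(0, 22))
        np.testing.assert_allclose(cov, np.cov(x, rowvar=False, ddof=0),
                                   atol=1e-12)

    def test_two_point_hand_oracle(self):
        x = np.array([[0.0, 0.0], [1.0, 2.0], [9.0, 9.0]])
        w = np.array([0.25, 0.75])
        cov = weighted_window_covariance(x, w, slice(0, 2))
        # mu = (0.75, 1.5); var1 = .25*.5625+.75*.0625 = 0.1875
        expected = np.array([[0.1875, 0.375], [0.375, 0.75]])
        np.testing.assert_allclose(cov, expected, atol=1e-12)

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((22, 14))
        w, _ = make_tapered_windows(170, TaperedWindowSpec())
        cov = weighted_window_covariance(x, w, slice(0, 22))
        assert np.linalg.eigvalsh(cov).min() > -1e-12

    def test_degenerate_weights_rejected(self):
        x = np.zeros((3, 2))
        with pytest.raises(ValueError):
            weighted_window_covariance(x, np.array([1.0, 0.0, 0.0]), slice(0, 3))
        with pytest.raises(ValueError):
            weighted_window_covariance(x, np.array([0.5, 0.6, -0.1]), slice(0, 3))


class TestStaticFC:
    def test_matches_corrcoef(self):
        rng = np.random.default_rng(3)
        tc = _tc(rng.standard_normal((170, 6)))
        z = static_fc(tc)
        r = np.corrcoef(tc.data, rowvar=False)
        iu = np.triu_indices(6, 1)
        np.testing.assert_allclose(z[iu], np.arctanh(r[iu]), atol=1e-10)
        np.testing.assert_array_equal(np.diag(z), 0.0)

    def test_constant_signal_rejected(self):
        data = np.random.default_rng(4).standard_normal((170, 3))
        data[:, 1] = 7.0
        with pytest.raises(ValueError, match="net2"):
            static_fc(_tc(data))


class TestGraphicalLasso:
    def test_zero_penalty_is_matrix_inverse(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((6, 6))
        s = a @ a.T / 6 + np.eye(6)
        w, theta = graphical_lasso(s, 0.0)
        np.testing.assert_allclose(theta, np.linalg.inv(s), atol=1e-10)
        np.testing.assert_allclose(w, s, atol=1e-12)

    def test_two_by_two_closed_form(self):
        # for S = [[1, r], [r, 1]] the penalized solution soft-thresholds the
        # off-diagonal covariance: w12 = r - lam (for 0 < lam < r)
        for r, lam in [(0.6, 0.1), (0.6, 0.3), (-0.5, 0.2)]:
            s = np.array([[1.0, r], [r, 1.0]])
            w, theta = graphical_lasso(s, lam, max_iter=500, tol=1e-10)
            shrunk = np.sign(r) * max(abs(r) - lam, 0.0)
            assert w[0, 1] == pytest.approx(shrunk, abs=1e-6)
            np.testing.assert_allclose(theta, np.linalg.inv(w), atol=1e-5)

    def test_large_penalty_gives_diagonal_precision(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((30, 5))
        s = np.corrcoef(a, rowvar=False)
        _, theta = graphical_lasso(s, 10.0, max_iter=500)
        off = theta - np.diag(np.diag(theta))
        assert np.max(np.abs(off)) < 1e-8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            graphical_lasso(np.array([[1.0, 0.2], [0.3, 1.0]]), 0.1)
        with pytest.raises(ValueError):
            graphical_lasso(np.eye(2), -0.1)
        with pytest.raises(ValueError):
            graphical_lasso(np.diag([1.0, 0.0]), 0.1)


class TestSelectPenalty:
    def test_single_grid_point_shortcut(self):
        covs = np.stack([np.eye(3)] * 4)
        assert select_penalty(covs, GlassoConfig(penalty_grid=[0.05])) == 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        covs = np.stack([np.cov(rng.standard_normal((22, 5)), rowvar=False)
                         + 0.5 * np.eye(5) for _ in range(20)])
        cfg = GlassoConfig(n_repeats=10)
        assert select_penalty(covs, cfg, seed=1) == select_penalty(covs, cfg,
                                                                   seed=1)

    def test_prefers_positive_penalty_for_sparse_truth(self):
        # short-window covariances of a sparse-precision Gaussian: CV should
        # pick a nonzero penalty most of the time
        wins = 0
        for trial in range(20):
            rng = np.random.default_rng(100 + trial)
            prec = np.eye(10)
            prec[0, 1] = prec[1, 0] = 0.4
            cov_true = np.linalg.inv(prec)
            l = np.linalg.cholesky(cov_true)
            covs = np.stack([
                np.cov(rng.standard_normal((15, 10)) @ l.T, rowvar=False,
                       ddof=0) + 1e-6 * np.eye(10)
                for _ in range(40)])
            lam = select_penalty(covs, GlassoConfig(n_repeats=10), seed=trial)
            wins += lam > 0
        assert wins >= 16  # >= 80 percent of trials

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            select_penalty(np.eye(3)[None], GlassoConfig())


class TestDynamicFC:
    def test_shapes_and_finiteness(self):
        rng = np.random.default_rng(8)
        tc = _tc(rng.standard_normal((170, 14)))
        stack = dynamic_fc(tc, TaperedWindowSpec(),
                           GlassoConfig(penalty_grid=[0.0]), seed=0)
        assert stack.edge_values.shape == (148, 91)
        assert np.all(np.isfinite(stack.edge_values))
        assert stack.n_windows == 148 and stack.n_edges == 91
        assert stack.selected_penalty == 0.0

    def test_window_centers_monotone(self):
        rng = np.random.default_rng(9)
        tc = _tc(rng.standard_normal((60, 4)))
        stack = dynamic_fc(tc, TaperedWindowSpec(),
                           GlassoConfig(penalty_grid=[0.0]), seed=0)
        assert np.all(np.diff(stack.window_centers) == 1.0)
        assert stack.window_centers[0] == pytest.approx(10.5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        tc = _tc(rng.standard_normal((60, 4)))
        a = dynamic_fc(tc, seed=5)
        b = dynamic_fc(tc, seed=5)
        np.testing.assert_array_equal(a.edge_values, b.edge_values)

    def test_strong_edge_recovered_in_every_window(self):
        # two strongly correlated networks: every windowed z should be
        # clearly positive on that edge
        rng = np.random.default_rng(11)
        base = rng.standard_normal(170)
        data = rng.standard_normal((170, 4)) * 0.2
        data[:, 0] += base
        data[:, 1] += base
        stack = dynamic_fc(_tc(data), TaperedWindowSpec(),
                           GlassoConfig(penalty_grid=[0.0]), seed=0)
        assert np.all(stack.edge_values[:, 0] > 0.5)


class TestResidualize:
    @staticmethod
    def _stacks_and_cov(n_sub=12, n_win=5, n_edges=6, seed=12):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n_sub)],
            "age": rng.uniform(30, 70, n_sub),
            "sex": rng.integers(0, 2, n_sub).astype(float),
            "education": rng.uniform(6, 18, n_sub),
            "mean_fd": rng.uniform(0.05, 0.3, n_sub),
        })
        labels = ["a", "b", "c", "d"]
        stacks = [
            WindowedFCStack(f"s{i}", rng.standard_normal((n_win, n_edges)),
                            labels, np.arange(n_win, dtype=float))
            for i in range(n_sub)]
        return stacks, cov

    def test_residuals_orthogonal_to_covariates(self):
        stacks, cov = self._stacks_and_cov()
        out = residualize_covariates(stacks, cov)
        x = cov[["age", "sex", "education", "mean_fd"]].to_numpy(float)
        xc = x - x.mean(axis=0)
        y = np.stack([s.edge_values.ravel() for s in out])
        assert np.max(np.abs(xc.T @ y)) < 1e-8

    def test_grand_mean_preserved(self):
        stacks, cov = self._stacks_and_cov()
        out = residualize_covariates(stacks, cov)
        before = np.mean([s.edge_values for s in stacks], axis=0)
        after = np.mean([s.edge_values for s in out], axis=0)
        np.testing.assert_allclose(after, before, atol=1e-10)

    def test_covariate_free_signal_unchanged(self):
        # edge values independent of covariates change only by the fitted
        # noise component; with a constant covariate the design reduces to an
        # intercept and values are exactly preserved
        stacks, cov = self._stacks_and_cov()
        cov[["age", "sex", "education", "mean_fd"]] = 1.0
        out = residualize_covariates(stacks, cov)
        for a, b in zip(stacks, out):
            np.testing.assert_allclose(a.edge_values, b.edge_values, atol=1e-12)

    def test_linear_covariate_effect_removed(self):
        stacks, cov = self._stacks_and_cov()
        age = cov["age"].to_numpy()
        spiked = []
        from dynfc.windows import WindowedFCStack
        for s, a in zip(stacks, age):
            ev = s.edge_values.copy()
            ev[:, 0] += 0.05 * a  # pure age effect on edge 0
            spiked.append(WindowedFCStack(s.subject_id, ev, s.network_labels,
                                          s.window_centers))
        out_plain = residualize_covariates(stacks, cov)
        out_spiked = residualize_covariates(spiked, cov)
        # the age component is removed but the grand mean of the spike stays;
        # compare after subtracting each run's grand mean on edge 0
        shift = np.mean([s.edge_values[:, 0] for s in out_spiked]) - \
            np.mean([s.edge_values[:, 0] for s in out_plain])
        for b in out_spiked:
            b.edge_values[:, 0] -= shift
        for a, b in zip(out_plain, out_spiked):
            np.testing.assert_allclose(a.edge_values, b.edge_values, atol=1e-9)

    def test_missing_covariate_rejected(self):
        stacks, cov = self._stacks_and_cov()
        cov.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="age"):
            residualize_covariates(stacks, cov)

    def test_shape_mismatch_rejected(self):
        stacks, cov = self._stacks_and_cov()
        from dynfc.windows import WindowedFCStack
        stacks[0] = WindowedFCStack("s0", stacks[0].edge_values[:3],
                                    stacks[0].network_labels,
                                    stacks[0].window_centers[:3])
        with pytest.raises(ValueError):
            residualize_covariates(stacks, cov)
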