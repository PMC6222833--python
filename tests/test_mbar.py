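import logging

import numpy as np
import pytest

import mbarwtp as m
from mbarwtp import mbar as mbar_mod


def _quadrature_df(system, windows):
    return m.window_free_energy_quadrature(system, windows[1]) - m.window_free_energy_quadrature(
        system, windows[0]
    )


class TestSolveMbar:
    def test_single_window_anchor(self, single_window_flat):
        sol = m.solve_mbar(single_window_flat)
        assert sol.converged
        assert sol.f_biased == pytest.approx([0.0])
        assert sol.n_iterations == 1

    def test_identical_windows_equal_free_energies(self):
        system = m.ToySystem.harmonic(seed=2)
        windows = [
            m.WindowSpec(0, (0.1, 0.0), (40.0, 40.0)),
            m.WindowSpec(1, (0.1, 0.0), (40.0, 40.0)),
        ]
        samples = m.sample_windows(system, windows, 800)
        sol = m.solve_mbar(samples)
        assert sol.f_biased[1] == pytest.approx(0.0, abs=0.1)

    def test_matches_quadrature_within_three_se(self, two_window_samples, two_window_solution):
        system, windows, samples = two_window_samples
        sol = two_window_solution
        df = sol.f_biased[1] - sol.f_biased[0]
        df_quad = _quadrature_df(system, windows)
        grid = m.Grid2D.from_range(-0.4, 0.4, 0.2)
        cov = m.fe_covariance(samples, sol, grid.assign(samples.rc))
        se = np.sqrt(cov.theta[0, 0] - 2 * cov.theta[0, 1] + cov.theta[1, 1])
        assert abs(df - df_quad) <= 3 * se

    def test_self_consistency_at_solution(self, two_window_samples, two_window_solution):
        _, _, samples = two_window_samples
        sol = two_window_solution
        rebuilt = mbar_mod.solution_from_f(samples, sol.f_biased)
        assert rebuilt.residual <= 1e-7

    def test_shift_invariance_of_weights(self, two_window_samples, two_window_solution):
        """Adding a constant to U_L changes no weight: the low-level energy
        cancels identically from the unbiased-weight expression."""
        _, _, samples = two_window_samples
        shifted = m.SampleSet(
            samples.windows, samples.window_index, samples.rc,
            samples.u_low + 137.0, samples.temperature, u_high=samples.u_high,
        )
        sol2 = m.solve_mbar(shifted)
        assert sol2.f_biased == pytest.approx(two_window_solution.f_biased, abs=1e-9)
        assert np.allclose(
            sol2.weights_normalized, two_window_solution.weights_normalized, atol=1e-12
        )

    def test_empty_window_rejected(self):
        windows = [
            m.WindowSpec(0, (0.0, 0.0), (1.0, 1.0)),
            m.WindowSpec(1, (1.0, 0.0), (1.0, 1.0)),
        ]
        ss = m.SampleSet(windows, np.zeros(5, dtype=int), np.zeros((5, 2)), np.zeros(5), 300.0)
        with pytest.raises(ValueError, match="empty"):
            m.solve_mbar(ss)

    def test_nonconvergence_raises_with_residual(self, two_window_samples):
        _, _, samples = two_window_samples
        with pytest.raises(m.MBARConvergenceError) as err:
            m.solve_mbar(samples, tol=1e-300, max_iter=3, solver="scf")
        assert err.value.residual > 0

    def test_scf_and_hybrid_agree(self, two_window_samples):
        _, _, samples = two_window_samples
        a = m.solve_mbar(samples, solver="hybrid")
        b = m.solve_mbar(samples, solver="scf")
        assert a.f_biased == pytest.approx(b.f_biased, abs=1e-6)


class TestBiasPathEquivalence:
    def test_grid_and_dense_paths_identical(self, two_window_samples):
        _, _, samples = two_window_samples
        grid_model = mbar_mod._make_bias_model(samples)
        dense_model = mbar_mod._DenseBias(samples)
        assert isinstance(grid_model, mbar_mod._GridBias)
        f = np.array([0.0, 0.37])
        og, cg, ldg, sg = grid_model.pass_through(f)
        od, cd, ldd, sd = dense_model.pass_through(f)
        assert og == pytest.approx(od)
        assert cg == pytest.approx(cd)
        assert np.allclose(ldg, ldd)
        assert sg == pytest.approx(sd)
        sl = slice(0, 50)
        assert np.allclose(
            grid_model.weight_matrix(f, ldg, sl), dense_model.weight_matrix(f, ldd, sl)
        )

    def test_non_product_layout_uses_dense_path(self):
        system = m.ToySystem.harmonic(seed=4)
        # centers not on a Cartesian product grid -> no Kronecker factorization
        windows = [
            m.WindowSpec(0, (-0.2, 0.0), (50.0, 50.0)),
            m.WindowSpec(1, (0.2, 0.1), (80.0, 50.0)),
        ]
        samples = m.sample_windows(system, windows, 400)
        assert isinstance(mbar_mod._make_bias_model(samples), mbar_mod._DenseBias)
        sol = m.solve_mbar(samples)
        assert sol.converged


class TestWeights:
    def test_flat_bias_uniform_weights(self, single_window_flat):
        sol = m.solve_mbar(single_window_flat)
        w = m.unbiased_weights(single_window_flat, sol, normalized=True)
        assert w == pytest.approx(np.full(single_window_flat.n_frames,
                                          1.0 / single_window_flat.n_frames))

    def test_weight_monotone_in_bias(self, two_window_samples, two_window_solution):
        """A frame near a restraint center is heavily biased there, so its
        unbiased weight must exceed that of a frame far from all centers."""
        _, windows, samples = two_window_samples
        near = np.array([[windows[0].center[0], windows[0].center[1]]])
        far = np.array([[1.5, 1.5]])
        f = two_window_solution.f_biased
        counts = samples.frame_counts.astype(float)

        def w0(pt):
            u = np.array([samples.beta * m.bias_energy(w, pt[0]) for w in samples.windows])
            return 1.0 / float((counts * np.exp(f - u)).sum())

        assert w0(near) < w0(far)  # far frame suppressed by no window -> larger w^0

    def test_weighted_mean_matches_quadrature(self, two_window_samples, two_window_solution):
        system, _, samples = two_window_samples
        w = m.unbiased_weights(samples, two_window_solution, normalized=True)
        est = float(w @ samples.rc[:, 0])
        # quadrature of <eta1> under the unbiased harmonic marginal: exactly 0
        se = float(np.sqrt((w**2 * (samples.rc[:, 0] - est) ** 2).sum()))
        assert est == pytest.approx(0.0, abs=3 * se)


class TestOverlap:
    def test_single_window_identity(self, single_window_flat):
        sol = m.solve_mbar(single_window_flat)
        assert m.overlap_matrix(single_window_flat, sol) == pytest.approx(np.array([[1.0]]))

    def test_rows_sum_to_one(self, two_window_samples, two_window_solution):
        _, _, samples = two_window_samples
        o = m.overlap_matrix(samples, two_window_solution)
        assert o.sum(axis=1) == pytest.approx(np.ones(2), abs=1e-10)
        assert np.all((o >= 0) & (o <= 1))

    def test_identical_windows_half_half(self):
        system = m.ToySystem.harmonic(seed=8)
        windows = [
            m.WindowSpec(0, (0.0, 0.0), (40.0, 40.0)),
            m.WindowSpec(1, (0.0, 0.0), (40.0, 40.0)),
        ]
        samples = m.sample_windows(system, windows, 2000)
        sol = m.solve_mbar(samples)
        o = m.overlap_matrix(samples, sol)
        assert o == pytest.approx(np.full((2, 2), 0.5), abs=0.02)

    def test_far_windows_warn_below_threshold(self, caplog):
        system = m.ToySystem.harmonic(k=(0.0, 0.0), seed=9)
        # stiff restraints ~10 sigma apart: essentially no shared configurations
        windows = [
            m.WindowSpec(0, (-1.0, 0.0), (400.0, 400.0)),
            m.WindowSpec(1, (1.0, 0.0), (400.0, 400.0)),
        ]
        samples = m.sample_windows(system, windows, 1500)
        sol = m.solve_mbar(samples)
        with caplog.at_level(logging.WARNING, logger="mbarwtp.mbar"):
            o = m.overlap_matrix(samples, sol)
        assert o[0, 1] < mbar_mod.OVERLAP_THRESHOLD
        assert any("0.03" in rec.getMessage() for rec in caplog.records)


class TestCovariance:
    def test_self_variance_zero_and_symmetry(self, bump_grid_data):
        _, samples, sol, grid = bump_grid_data
        cov = m.fe_covariance(samples, sol, grid.assign(samples.rc))
        a = int(cov.bin_ids[0])
        b = int(cov.bin_ids[-1])
        assert cov.delta2_f(a, a) == 0.0
        assert cov.delta2_f(a, b) == pytest.approx(cov.delta2_f(b, a))
        assert np.allclose(cov.theta, cov.theta.T)

    def test_positive_between_distinct_bins(self, bump_grid_data):
        _, samples, sol, grid = bump_grid_data
        cov = m.fe_covariance(samples, sol, grid.assign(samples.rc))
        assert cov.delta2_f(int(cov.bin_ids[0]), int(cov.bin_ids[-1])) > 0

    def test_degenerate_window_flagged(self, caplog):
        windows = [m.WindowSpec(0, (0.0, 0.0), (0.0, 0.0))]
        rc = np.tile([[0.1, 0.1]], (10, 1))
        ss = m.SampleSet(windows, np.zeros(10, dtype=int), rc, np.zeros(10), 300.0)
        sol = m.solve_mbar(ss)
        grid = m.Grid2D.from_range(0.0, 0.2, 0.2)
        with caplog.at_level(logging.WARNING, logger="mbarwtp.mbar"):
            m.fe_covariance(ss, sol, grid.assign(ss.rc))
        assert any("unreliable" in rec.getMessage() for rec in caplog.records)


def test_diagnostics_report_is_json_ready(two_window_samples, two_window_solution):
    import json

    _, _, samples = two_window_samples
    o = m.overlap_matrix(samples, two_window_solution)
    report = m.diagnostics_report(samples, two_window_solution, o)
    text = json.dumps(report)
    assert "overlap_matrix" in text and report["converged"]
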