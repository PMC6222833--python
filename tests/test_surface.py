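import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mbarwtp as m
from mbarwtp.surface import DOMINANCE_LIMIT


def _flat_set(rc, u_low, u_high=None, obs=None):
    """Single zero-bias window: every frame has equal unbiased weight."""
    n = len(u_low)
    windows = [m.WindowSpec(0, (0.0, 0.0), (0.0, 0.0))]
    return m.SampleSet(
        windows, np.zeros(n, dtype=int), rc, np.asarray(u_low, float), 298.15,
        u_high=None if u_high is None else np.asarray(u_high, float),
        observables=obs,
    )


class TestLowLevelSurface:
    def test_count_ratio_gives_ln2(self):
        """Equal weights, bins with n and 2n frames: dF = -kT ln 2."""
        n = 200
        rc = np.concatenate([
            np.tile([[0.0, 0.0]], (n, 1)),
            np.tile([[1.0, 0.0]], (2 * n, 1)),
        ])
        ss = _flat_set(rc, np.zeros(3 * n))
        sol = m.solve_mbar(ss)
        grid = m.Grid2D.from_range(0.0, 1.0, 1.0)
        surf = m.fe_surface_low(ss, sol, grid, anchor=(0, 0))
        expected = -np.log(2.0) / ss.beta
        assert surf.value[1, 0] == pytest.approx(expected, abs=1e-12)

    def test_shift_invariance(self, bump_grid_data):
        _, samples, sol, grid = bump_grid_data
        shifted = m.SampleSet(
            samples.windows, samples.window_index, samples.rc,
            samples.u_low + 55.5, samples.temperature, u_high=samples.u_high,
        )
        sol2 = m.solve_mbar(shifted)
        a = m.fe_surface_low(samples, sol, grid, anchor=(2, 2))
        b = m.fe_surface_low(shifted, sol2, grid, anchor=(2, 2))
        assert np.allclose(a.value[a.occupied], b.value[b.occupied], atol=1e-9)

    def test_recovers_analytic_harmonic_marginal(self, bump_grid_data):
        system, samples, sol, grid = bump_grid_data
        est = m.fe_surface_low(samples, sol, grid, anchor=(2, 2))
        ana = m.analytic_surface(system, grid, "low", anchor=(2, 2))
        rmse = np.sqrt(np.mean((est.value[est.occupied] - ana.value[est.occupied]) ** 2))
        assert rmse <= 0.1

    def test_unoccupied_anchor_rejected(self, bump_grid_data):
        _, samples, sol, _ = bump_grid_data
        wide = m.Grid2D.from_range(-2.0, 2.0, 0.2)
        with pytest.raises(ValueError, match="unoccupied"):
            m.fe_surface_low(samples, sol, wide, anchor=(0, 0))


class TestReweightingEntropy:
    def test_uniform_is_one(self):
        assert m.reweighting_entropy(np.ones(7)) == pytest.approx(1.0)

    def test_degenerate_is_zero(self):
        assert m.reweighting_entropy([1.0, 0.0, 0.0]) == pytest.approx(0.0)

    def test_single_frame_convention(self):
        assert m.reweighting_entropy([0.42]) == 1.0

    def test_half_quarter_quarter(self):
        expected = np.log(2.0 * np.sqrt(2.0)) / np.log(3.0)  # 0.946395...
        assert m.reweighting_entropy([0.5, 0.25, 0.25]) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            m.reweighting_entropy([0.0, 0.0])

    @given(st.lists(st.floats(1e-6, 1e3), min_size=2, max_size=30))
    def test_bounded_in_unit_interval(self, weights):
        s = m.reweighting_entropy(weights)
        assert -1e-12 <= s <= 1.0 + 1e-12


class TestWTP:
    def test_identical_hamiltonians_zero_exact(self, bump_grid_data):
        _, samples, sol, grid = bump_grid_data
        same = m.SampleSet(
            samples.windows, samples.window_index, samples.rc, samples.u_low,
            samples.temperature, u_high=samples.u_low.copy(),
        )
        res = m.wtp_correct(same, sol, grid)
        assert np.allclose(res.delta_f.value[res.delta_f.occupied], 0.0, atol=1e-10)

    def test_constant_offset_exact(self, bump_grid_data):
        _, samples, sol, grid = bump_grid_data
        c = 2.75
        shifted = m.SampleSet(
            samples.windows, samples.window_index, samples.rc, samples.u_low,
            samples.temperature, u_high=samples.u_low + c,
        )
        res = m.wtp_correct(shifted, sol, grid)
        assert np.allclose(res.delta_f.value[res.delta_f.occupied], c, atol=1e-10)

    def test_additivity_by_construction(self, bump_grid_data):
        _, samples, sol, grid = bump_grid_data
        res = m.wtp_correct(samples, sol, grid)
        occ = res.f_high.occupied
        assert np.allclose(
            res.f_high.value[occ], res.f_low.value[occ] + res.delta_f.value[occ], atol=1e-12
        )

    def test_recovers_smooth_perturbation_within_3se(self, bump_grid_data):
        system, samples, sol, grid = bump_grid_data
        res = m.wtp_correct(samples, sol, grid)
        expected = m.analytic_wtp_delta(system, grid)
        occ = res.delta_f.occupied
        err = res.delta_f.value[occ] - expected[occ]
        se = np.sqrt(res.delta_f.variance[occ])
        assert np.all(np.abs(err) <= 3 * se)

    def test_common_shift_invariance(self, bump_grid_data):
        """Adding the same constant to U_L and U_H leaves the correction unchanged."""
        _, samples, sol, grid = bump_grid_data
        shifted = m.SampleSet(
            samples.windows, samples.window_index, samples.rc, samples.u_low + 9.0,
            samples.temperature, u_high=samples.u_high + 9.0,
        )
        sol2 = m.solve_mbar(shifted)
        a = m.wtp_correct(samples, sol, grid)
        b = m.wtp_correct(shifted, sol2, grid)
        occ = a.delta_f.occupied
        assert np.allclose(a.delta_f.value[occ], b.delta_f.value[occ], atol=1e-9)

    def test_jensen_bound(self, bump_grid_data):
        """Exponential averaging never exceeds the weighted mean energy gap."""
        _, samples, sol, grid = bump_grid_data
        res = m.wtp_correct(samples, sol, grid)
        gap = m.SampleSet(
            samples.windows, samples.window_index, samples.rc, samples.u_low,
            samples.temperature, u_high=samples.u_high,
            observables={"gap": samples.u_high - samples.u_low},
        )
        mean_gap, _ = m.reweighted_observable(gap, sol, grid, "gap", level="low")
        occ = res.delta_f.occupied
        assert np.all(res.delta_f.value[occ] <= mean_gap.value[occ] + 1e-9)

    def test_missing_u_high_names_bin(self, bump_grid_data):
        _, samples, sol, grid = bump_grid_data
        broken = samples.u_high.copy()
        broken[0] = np.nan
        bad = m.SampleSet(
            samples.windows, samples.window_index, samples.rc, samples.u_low,
            samples.temperature, u_high=broken,
        )
        with pytest.raises(ValueError, match=r"bin \(\d+, \d+\)"):
            m.wtp_correct(bad, sol, grid)

    def test_dominated_bin_flagged(self):
        rc = np.tile([[0.0, 0.0]], (5, 1))
        u_high = np.array([0.0, 1e4, 1e4, 1e4, 1e4])
        ss = _flat_set(rc, np.zeros(5), u_high=u_high)
        sol = m.solve_mbar(ss)
        grid = m.Grid2D.from_range(0.0, 0.0 + 0.2, 0.2)
        res = m.wtp_correct(ss, sol, grid)
        assert res.dominated.any()
        assert res.entropy[res.delta_f.occupied].min() < 0.05
        assert DOMINANCE_LIMIT < 1.0


class TestReweightedObservable:
    def test_constant_observable(self, bump_grid_data):
        _, samples, sol, grid = bump_grid_data
        cset = m.SampleSet(
            samples.windows, samples.window_index, samples.rc, samples.u_low,
            samples.temperature, u_high=samples.u_high,
            observables={"c": np.full(samples.n_frames, 4.2)},
        )
        mean, var = m.reweighted_observable(cset, sol, grid, "c")
        occ = mean.occupied
        assert np.allclose(mean.value[occ], 4.2)
        assert np.allclose(var.value[occ], 0.0, atol=1e-12)

    def test_equal_weights_arithmetic_mean(self):
        rng = np.random.default_rng(1)
        rc = np.column_stack([rng.uniform(-0.05, 0.05, 100), rng.uniform(-0.05, 0.05, 100)])
        obs = rng.normal(size=100)
        ss = _flat_set(rc, np.zeros(100), u_high=np.zeros(100), obs={"o": obs})
        sol = m.solve_mbar(ss)
        grid = m.Grid2D.from_range(-0.05, 0.15, 0.2)
        mean, var = m.reweighted_observable(ss, sol, grid, "o")
        assert mean.value[0, 0] == pytest.approx(obs.mean())
        assert var.value[0, 0] == pytest.approx(obs.var(), rel=1e-9)

    def test_reweighted_mean_matches_brute_force(self, bump_grid_data):
        """Direct-summation oracle: the perturbation-weighted bin average recomputed naively."""
        _, samples, sol, grid = bump_grid_data
        oset = m.SampleSet(
            samples.windows, samples.window_index, samples.rc, samples.u_low,
            samples.temperature, u_high=samples.u_high,
            observables={"eta1": samples.rc[:, 0].copy()},
        )
        mean, _ = m.reweighted_observable(oset, sol, grid, "eta1")
        bins = grid.assign(samples.rc)
        w0 = sol.weights_unbiased
        boltz = w0 * np.exp(-samples.beta * (samples.u_high - samples.u_low))
        b = int(bins[0])
        mask = bins == b
        brute = (boltz[mask] * samples.rc[mask, 0]).sum() / boltz[mask].sum()
        i, j = grid.unravel(b)
        assert mean.value[i, j] == pytest.approx(brute, rel=1e-9)

    def test_missing_observable_rejected(self, bump_grid_data):
        _, samples, sol, grid = bump_grid_data
        with pytest.raises(ValueError, match="not present"):
            m.reweighted_observable(samples, sol, grid, "nope")

    def test_variance_zero_iff_constant(self, bump_grid_data):
        _, samples, sol, grid = bump_grid_data
        oset = m.SampleSet(
            samples.windows, samples.window_index, samples.rc, samples.u_low,
            samples.temperature, u_high=samples.u_high,
            observables={"eta2": samples.rc[:, 1].copy()},
        )
        _, var = m.reweighted_observable(oset, sol, grid, "eta2")
        occ = var.occupied & (var.count > 1)
        assert np.all(var.value[occ] > 0)
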